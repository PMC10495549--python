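"""Haplotype collapse and minimum-spanning networks for aligned sequences.

Sanger-sequenced nuclear and chloroplast amplicons from a subset of
individuals are collapsed into haplotypes after discarding alignment columns
containing ambiguous residues or gaps in *any* record (complete-deletion
convention).  Relationships among haplotypes are exported as a Hamming
minimum-spanning network: a minimum spanning tree augmented with every edge
that ties the joining weight between two components at the moment they are
merged, so alternative equally-parsimonious connections are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import SeqIO

AMBIGUOUS = frozenset("N-")
VALID = frozenset("ACGTN-")

__all__ = [
    "Alignment",
    "HaplotypeSet",
    "read_fasta_alignment",
    "collapse_haplotypes",
    "count_variable_sites",
    "hamming_msn",
    "minimum_spanning_network",
]


@dataclass(frozen=True)
class Alignment:
    """A set of equal-length sequences over {A,C,G,T,N,-}."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one record")
        L = len(self.records[0][1])
        for label, seq in self.records:
            if len(seq) != L:
                raise ValueError(
                    f"ragged alignment: {label!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq.upper()) - VALID
            if bad:
                raise ValueError(f"{label!r}: invalid residues {sorted(bad)}")
        if L < 1:
            raise ValueError("alignment length must be >= 1")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def labels(self) -> list[str]:
        return [r[0] for r in self.records]

    def matrix(self) -> np.ndarray:
        """(n_records, length) array of single characters, upper-cased."""
        return np.array([list(seq.upper()) for _, seq in self.records])

    def retained_sites(self) -> np.ndarray:
        """Boolean mask of columns free of N/- in every record."""
        m = self.matrix()
        return ~np.isin(m, list(AMBIGUOUS)).any(axis=0)


@dataclass(frozen=True)
class Haplotype:
    sequence: str
    count: int
    member_labels: tuple[str, ...]
    tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class HaplotypeSet:
    haplotypes: tuple[Haplotype, ...]

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]


def read_fasta_alignment(path: str | Path) -> Alignment:
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    return Alignment(records=records)


def collapse_haplotypes(
    aln: Alignment, tags: Mapping[str, str] | None = None
) -> HaplotypeSet:
    """Merge records identical over the retained (unambiguous) sites.

    ``tags`` optionally maps record label -> categorical tag (e.g. host
    crop); each haplotype carries the tags of its members, ordered by first
    appearance.  Haplotypes are ordered by descending count then first
    appearance, and their ``sequence`` is the full-length sequence of the
    first member.
    """
    keep = aln.retained_sites()
    m = aln.matrix()
    keys = ["".join(row) for row in m[:, keep]]
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    haps = []
    for k, idx in groups.items():
        labels = tuple(aln.records[i][0] for i in idx)
        tg: list[str] = []
        if tags:
            for lab in labels:
                t = tags.get(lab)
                if t is not None and t not in tg:
                    tg.append(t)
        haps.append(
            Haplotype(
                sequence=aln.records[idx[0]][1],
                count=len(idx),
                member_labels=labels,
                tags=tuple(tg),
            )
        )
    haps.sort(key=lambda h: (-h.count, aln.labels.index(h.member_labels[0])))
    return HaplotypeSet(haplotypes=tuple(haps))


def count_variable_sites(aln: Alignment) -> tuple[int, float]:
    """Number and fraction of retained columns with >= 2 distinct residues.

    Columns containing N or a gap anywhere are not counted as variable (they
    are excluded from comparison entirely); the fraction is relative to the
    full alignment length.
    """
    keep = aln.retained_sites()
    m = aln.matrix()[:, keep]
    n_var = int(sum(len(set(m[:, j])) >= 2 for j in range(m.shape[1])))
    return n_var, n_var / aln.length


def _hamming(a: str, b: str, keep: np.ndarray) -> int:
    aa = np.frombuffer(a.upper().encode(), dtype="S1")
    bb = np.frombuffer(b.upper().encode(), dtype="S1")
    return int((aa[keep] != bb[keep]).sum())


def minimum_spanning_network(
    labels: Sequence[str], dist: np.ndarray
) -> nx.Graph:
    """Minimum spanning network: union of all minimum spanning trees' edges.

    Kruskal-style construction with tie retention: edges are scanned in
    weight order; within one weight class, every edge joining two components
    that were distinct *before* the class was processed is kept.  The result
    contains at least one MST, and any spanning tree inside it using only
    kept edges of minimal joining weights has minimum total weight.
    """
    n = len(labels)
    g = nx.Graph()
    g.add_nodes_from(labels)
    if n <= 1:
        return g
    edges = sorted(
        ((dist[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: e[0],
    )
    from networkx.utils import UnionFind

    uf = UnionFind(range(n))
    k = 0
    while k < len(edges):
        w = edges[k][0]
        # snapshot of components before this weight class
        comp_before = {i: uf[i] for i in range(n)}
        batch = []
        while k < len(edges) and edges[k][0] == w:
            _, i, j = edges[k]
            if comp_before[i] != comp_before[j]:
                batch.append((i, j))
            k += 1
        for i, j in batch:
            g.add_edge(labels[i], labels[j], weight=float(w))
            uf.union(i, j)
    return g


def hamming_msn(hs: HaplotypeSet, aln: Alignment | None = None) -> nx.Graph:
    """Minimum spanning network over haplotypes with Hamming-distance weights.

    Distances are computed over sites free of N/- in the *haplotype set*
    (or, when ``aln`` is given, the same retained-site mask as the source
    alignment, so weights agree with the collapse step).  Nodes are labelled
    ``H1..Hk`` with ``count`` and ``tags`` attributes.
    """
    seqs = [h.sequence for h in hs.haplotypes]
    sub = Alignment(records=tuple((f"H{i+1}", s) for i, s in enumerate(seqs)))
    keep = (aln or sub).retained_sites()
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _hamming(seqs[i], seqs[j], keep)
    labels = [f"H{i+1}" for i in range(n)]
    g = minimum_spanning_network(labels, dist)
    for i, h in enumerate(hs.haplotypes):
        g.nodes[labels[i]]["count"] = h.count
        g.nodes[labels[i]]["tags"] = ",".join(h.tags)
    return g


def write_network(g: nx.Graph, path: str | Path, format: str = "tsv") -> Path:
    """Export a network as a TSV edge list or GraphML."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "tsv":
        with path.open("w") as fh:
            fh.write("from\tto\tweight\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):g}\n")
    else:
        raise ValueError(f"unsupported format {format!r}")
    return path


def write_haplotype_table(hs: HaplotypeSet, path: str | Path) -> Path:
    import hashlib

    path = Path(path)
    with path.open("w") as fh:
        fh.write("haplotype\tsequence_sha1\tcount\ttags\tmembers\n")
        for i, h in enumerate(hs.haplotypes):
            digest = hashlib.sha1(h.sequence.encode()).hexdigest()[:12]
            fh.write(
                f"H{i+1}\t{digest}\t{h.count}\t{','.join(h.tags)}\t"
                f"{','.join(h.member_labels)}\n"
            )
    return path
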