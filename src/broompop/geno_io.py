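"""Data model and GenAlEx-style I/O for codominant microsatellite genotypes.

The central container is :class:`GenotypeDataset`: an individuals x loci
matrix of unordered diploid allele-size pairs plus per-individual metadata
(field population, host crop, coordinates).  A "population" is the set of
individuals collected in one agricultural field growing a single host crop,
so the population -> host mapping must be a function; this is asserted on
construction.

Files follow the GenAlEx codominant convention: two columns per locus,
allele sizes as integers, 0 (or an empty cell) meaning a missing call.
Internally missing calls use the sentinel :data:`MISSING` (-1) so that 0 can
never be confused with an allele state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "LocusDef",
    "SampleMeta",
    "GenotypeDataset",
    "read_genotypes",
    "write_genotypes",
    "filter_complete",
    "subset_min_n",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the expected schema."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus.

    ``motif_length`` is the repeat-unit size in bp; allele sizes are
    converted to repeat counts as ``(size - offset) / motif_length``, which
    is what Bruvo distance and the stepwise mutation simulator operate on.
    ``allele_range`` bounds the allele *size* states (inclusive).
    """

    name: str
    motif_length: int = 1
    allele_range: tuple[int, int] = (1, 10_000)
    offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"locus {self.name}: motif_length must be >= 1")
        lo, hi = self.allele_range
        if not lo < hi:
            raise ValueError(f"locus {self.name}: allele_range lower must be < upper")

    def to_repeats(self, sizes: np.ndarray) -> np.ndarray:
        """Convert allele sizes (bp) to repeat counts; MISSING passes through."""
        out = np.where(sizes == MISSING, MISSING, (sizes - self.offset) // self.motif_length)
        return out


@dataclass(frozen=True)
class SampleMeta:
    individual_id: str
    population_id: str
    host_crop: str = ""
    country: str = ""
    latitude: float | None = None
    longitude: float | None = None
    year: int | None = None


@dataclass
class GenotypeDataset:
    """Diploid allele-size matrix with sample metadata.

    ``calls`` has shape (n_individuals, n_loci, 2); each pair is stored
    sorted ascending (codominant data has no phase) with both entries
    MISSING when the call failed.
    """

    loci: list[LocusDef]
    samples: list[SampleMeta]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.samples), len(self.loci)
        if n < 1 or L < 1:
            raise ValueError("dataset needs at least 1 individual and 1 locus")
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        # normalize pair order; a half-missing pair becomes fully missing
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        ids = [s.individual_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("individual_id values must be unique")
        host_of: dict[str, str] = {}
        for s in self.samples:
            prev = host_of.setdefault(s.population_id, s.host_crop)
            if prev != s.host_crop:
                raise ValueError(
                    f"population {s.population_id!r} maps to two hosts: "
                    f"{prev!r} and {s.host_crop!r}"
                )
        for j, locus in enumerate(self.loci):
            col = self.calls[:, j, :]
            ok = (col == MISSING) | (
                (col >= locus.allele_range[0]) & (col <= locus.allele_range[1])
            )
            if not ok.all():
                bad = col[~ok][0]
                raise ValueError(
                    f"allele {bad} outside allele_range of locus {locus.name}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population_id, None)
        return list(seen)

    @property
    def populations(self) -> dict[str, np.ndarray]:
        """population_id -> index array of member individuals."""
        idx: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            idx.setdefault(s.population_id, []).append(i)
        return {p: np.asarray(v, dtype=np.intp) for p, v in idx.items()}

    @property
    def host_of_population(self) -> dict[str, str]:
        return {s.population_id: s.host_crop for s in self.samples}

    def repeat_calls(self) -> np.ndarray:
        """calls converted to repeat counts per locus (MISSING preserved)."""
        out = np.empty_like(self.calls)
        for j, locus in enumerate(self.loci):
            out[:, j, :] = locus.to_repeats(self.calls[:, j, :])
        return out

    def take(self, indices: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeDataset(
            loci=list(self.loci),
            samples=[self.samples[i] for i in indices],
            calls=self.calls[indices].copy(),
        )

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [s.individual_id for s in self.samples],
                "population_id": [s.population_id for s in self.samples],
                "host_crop": [s.host_crop for s in self.samples],
                "country": [s.country for s in self.samples],
                "latitude": [s.latitude for s in self.samples],
                "longitude": [s.longitude for s in self.samples],
                "year": [s.year for s in self.samples],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_allele(cell: str, line_no: int, col_no: int) -> int:
    cell = cell.strip()
    if cell in ("", "0"):
        return MISSING
    try:
        v = int(cell)
    except ValueError:
        raise GenotypeParseError(
            f"non-integer allele {cell!r} at line {line_no}, column {col_no}"
        ) from None
    return MISSING if v == 0 else v


def read_genotypes(
    path: str | Path,
    format: str = "genalex_csv",
    *,
    meta_path: str | Path | None = None,
    loci: Sequence[LocusDef] | None = None,
    delimiter: str = ",",
) -> GenotypeDataset:
    """Read a GenAlEx-style codominant CSV.

    Layout: row 1 = ``n_loci, n_samples, n_pops, size_1, ..., size_npops``;
    row 2 = title then population labels; row 3 = column header with one
    locus name per allele-column pair; data rows = individual id,
    population id, then two allele columns per locus.  0/empty = missing.

    ``meta_path`` optionally points to a side-table CSV with columns
    individual_id, population_id, host_crop, country, lat, lon, year.
    ``loci`` optionally supplies full locus definitions (motif lengths,
    allele ranges); names must then match the file header.
    """
    if format != "genalex_csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if len(rows) < 4:
        raise GenotypeParseError(f"{path}: expected >= 4 rows, got {len(rows)}")
    try:
        n_loci = int(rows[0][0])
        n_samples = int(rows[0][1])
    except (IndexError, ValueError):
        raise GenotypeParseError(f"{path}: malformed count header at line 1") from None
    header = rows[2]
    if len(header) < 2 + 2 * n_loci:
        raise GenotypeParseError(
            f"{path}: header at line 3 declares fewer than {2 * n_loci} allele columns"
        )
    locus_names = [header[2 + 2 * j].strip() for j in range(n_loci)]
    if loci is not None:
        by_name = {l.name: l for l in loci}
        try:
            locus_defs = [by_name[nm] for nm in locus_names]
        except KeyError as e:
            raise GenotypeParseError(f"{path}: locus {e.args[0]!r} not in provided loci") from None
    else:
        locus_defs = [LocusDef(name=nm) for nm in locus_names]

    meta_by_id: dict[str, dict] = {}
    if meta_path is not None:
        mdf = pd.read_csv(
            meta_path,
            dtype={"individual_id": str, "population_id": str},
            float_precision="round_trip",
        )
        meta_by_id = {str(r["individual_id"]): r for _, r in mdf.iterrows()}

    samples: list[SampleMeta] = []
    calls = np.full((n_samples, n_loci, 2), MISSING, dtype=np.int64)
    data_rows = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data_rows) != n_samples:
        raise GenotypeParseError(
            f"{path}: header declares {n_samples} samples, found {len(data_rows)} data rows"
        )
    for i, row in enumerate(data_rows):
        line_no = 4 + i
        if len(row) < 2 + 2 * n_loci:
            raise GenotypeParseError(
                f"{path}: line {line_no} has {len(row)} columns, expected >= {2 + 2 * n_loci}"
            )
        ind_id, pop_id = row[0].strip(), row[1].strip()
        m = meta_by_id.get(ind_id)
        if m is not None:
            def _f(key):
                v = m.get(key)
                return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

            lat, lon, year = _f("lat"), _f("lon"), _f("year")
            samples.append(
                SampleMeta(
                    individual_id=ind_id,
                    population_id=pop_id,
                    host_crop=str(_f("host_crop") or ""),
                    country=str(_f("country") or ""),
                    latitude=None if lat is None else float(lat),
                    longitude=None if lon is None else float(lon),
                    year=None if year is None else int(year),
                )
            )
        else:
            samples.append(SampleMeta(individual_id=ind_id, population_id=pop_id))
        for j in range(n_loci):
            a = _parse_allele(row[2 + 2 * j], line_no, 3 + 2 * j)
            b = _parse_allele(row[3 + 2 * j], line_no, 4 + 2 * j)
            calls[i, j] = (a, b)
    return GenotypeDataset(loci=locus_defs, samples=samples, calls=calls)


def write_genotypes(
    ds: GenotypeDataset,
    path: str | Path,
    format: str = "genalex_csv",
    *,
    title: str = "broompop export",
    delimiter: str = ",",
) -> Path:
    """Write a dataset as GenAlEx-style CSV (missing encoded as 0).

    ``read_genotypes(write_genotypes(ds))`` reproduces ``ds`` up to locus
    definitions (motif lengths are not stored in the GenAlEx format; pass
    ``loci=ds.loci`` when re-reading to recover them).
    """
    if format != "genalex_csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    pops = ds.population_ids
    pop_sizes = {p: 0 for p in pops}
    for s in ds.samples:
        pop_sizes[s.population_id] += 1
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow([ds.n_loci, ds.n_individuals, len(pops)] + [pop_sizes[p] for p in pops])
        w.writerow([title, ""] + pops)
        header = ["Ind", "Pop"]
        for locus in ds.loci:
            header += [locus.name, ""]
        w.writerow(header)
        enc = np.where(ds.calls == MISSING, 0, ds.calls)
        for i, s in enumerate(ds.samples):
            row: list = [s.individual_id, s.population_id]
            for j in range(ds.n_loci):
                row += [int(enc[i, j, 0]), int(enc[i, j, 1])]
            w.writerow(row)
    return path


def write_metadata(ds: GenotypeDataset, path: str | Path) -> Path:
    """Write the metadata side-table consumed by ``read_genotypes(meta_path=...)``."""
    df = ds.metadata_frame().rename(columns={"latitude": "lat", "longitude": "lon"})
    df.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_complete(ds: GenotypeDataset) -> GenotypeDataset:
    """Keep only individuals with no missing call at any locus (idempotent)."""
    keep = ~(ds.calls == MISSING).any(axis=(1, 2))
    return ds.take(np.flatnonzero(keep)) if not keep.all() else ds.take(np.arange(ds.n_individuals))


def subset_min_n(ds: GenotypeDataset, min_n: int) -> GenotypeDataset:
    """Keep only populations with at least ``min_n`` genotyped individuals."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    sizes: dict[str, int] = {}
    for s in ds.samples:
        sizes[s.population_id] = sizes.get(s.population_id, 0) + 1
    keep = [i for i, s in enumerate(ds.samples) if sizes[s.population_id] >= min_n]
    return ds.take(keep)
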