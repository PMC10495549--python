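"""Discriminant analysis of principal components (DAPC) for genotype data.

Individuals are encoded as allele-count vectors (0/1/2 per allele column),
centred, and reduced by PCA.  Cluster search runs k-means on the retained
principal components and scores each K with BIC = n*ln(WSS/n) + K*ln(n);
the discriminant step fits a linear discriminant analysis on the retained
PCs and reports per-individual membership coefficients (posterior
probabilities, rows summing to 1).  The a-score criterion — observed
correct-reassignment rate minus its expectation under random cluster
relabelings — guards against retaining so many PCs that the discriminant
functions overfit.  No Hardy-Weinberg or linkage assumptions are made,
which suits a predominantly selfing organism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .geno_io import MISSING, GenotypeDataset

__all__ = [
    "ClusterModel",
    "allele_count_matrix",
    "pca_scores",
    "find_clusters",
    "fit_dapc",
    "optimize_ascore",
    "categorize_individuals",
]


@dataclass
class ClusterModel:
    """Fitted DAPC model: assignments, memberships and bookkeeping."""

    memberships: pd.DataFrame  # individuals x K, rows sum to 1
    assignments: pd.Series  # hard labels (argmax membership)
    n_pca: int
    n_da: int
    bic: pd.Series | None = None  # BIC per K from the cluster search
    ascore: pd.Series | None = None  # a-score per candidate n_pca

    @property
    def k(self) -> int:
        return self.memberships.shape[1]


def allele_count_matrix(ds: GenotypeDataset) -> tuple[np.ndarray, list[str]]:
    """Individuals x alleles matrix of allele counts (0/1/2), mean-imputed.

    One column per (locus, allele) pair observed in the dataset; missing
    calls are imputed with the column mean so they are neutral after
    centering.
    """
    blocks = []
    names = []
    for j, locus in enumerate(ds.loci):
        col = ds.calls[:, j, :]
        alleles = np.unique(col[col != MISSING])
        block = np.zeros((ds.n_individuals, len(alleles)))
        typed = col[:, 0] != MISSING
        for ai, a in enumerate(alleles):
            block[typed, ai] = (col[typed] == a).sum(axis=1)
        if (~typed).any() and typed.any():
            block[~typed] = block[typed].mean(axis=0)
        blocks.append(block)
        names.extend(f"{locus.name}.{a}" for a in alleles)
    return np.hstack(blocks), names


def pca_scores(
    x: np.ndarray, n_pca: int | None = None, var_target: float = 0.90
) -> np.ndarray:
    """Centered PCA scores; defaults to enough axes for ``var_target`` variance."""
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    nonzero = var > 1e-12 * var.max() if var.max() > 0 else var > -1
    u, s, var = u[:, nonzero], s[nonzero], var[nonzero]
    if n_pca is None:
        frac = np.cumsum(var) / var.sum()
        n_pca = int(np.searchsorted(frac, var_target) + 1)
    n_pca = min(n_pca, len(s))
    return u[:, :n_pca] * s[:n_pca]


def find_clusters(
    ds: GenotypeDataset,
    k_max: int,
    seed: int | np.random.Generator = 0,
    *,
    n_pca: int | None = None,
    n_restarts: int = 10,
) -> tuple[pd.Series, dict[int, np.ndarray]]:
    """K-means cluster search on retained PCs with a BIC curve.

    Returns (BIC per K for K=1..k_max, hard assignments per K).  BIC(K) =
    n*ln(WSS_K/n) + K*ln(n) computed on the retained principal components;
    k-means uses ``n_restarts`` restarts and is reproducible under the seed.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if ds.n_individuals < k_max:
        raise ValueError("more clusters requested than individuals")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x, _ = allele_count_matrix(ds)
    scores = pca_scores(x, n_pca=n_pca)
    n = scores.shape[0]
    bic = {}
    assignments: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=n_restarts,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(scores)
            wss = float(km.inertia_)
            labels = km.labels_
        bic[k] = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
        assignments[k] = labels
    return pd.Series(bic, name="BIC"), assignments


def fit_dapc(
    ds: GenotypeDataset,
    assignments: Sequence[int] | np.ndarray,
    n_pca: int,
    n_da: int | None = None,
) -> ClusterModel:
    """Linear discriminant analysis on retained PCs with membership posteriors."""
    labels = np.asarray(assignments)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("discriminant step needs K >= 2 clusters")
    if n_pca < 1:
        raise ValueError("n_pca must be >= 1")
    if n_pca >= ds.n_individuals:
        raise ValueError("n_pca must be smaller than the number of individuals")
    x, _ = allele_count_matrix(ds)
    scores = pca_scores(x, n_pca=n_pca)
    n_da = min(n_da or k - 1, k - 1)
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    lda.fit(scores, labels)
    proba = lda.predict_proba(scores)
    ids = [s.individual_id for s in ds.samples]
    memberships = pd.DataFrame(proba, index=ids, columns=lda.classes_)
    hard = pd.Series(memberships.idxmax(axis=1), index=ids, name="cluster")
    return ClusterModel(
        memberships=memberships,
        assignments=hard,
        n_pca=scores.shape[1],
        n_da=n_da,
    )


def optimize_ascore(
    ds: GenotypeDataset,
    assignments: Sequence[int] | np.ndarray,
    grid: Sequence[int],
    n_rand: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[int, pd.Series]:
    """Pick the number of PCs for the discriminant step by the a-score.

    a-score(n_pca) = mean over clusters of (observed correct-reassignment
    proportion - mean proportion under ``n_rand`` random relabelings).
    Returns (best n_pca, a-score per candidate).
    """
    if not grid:
        raise ValueError("candidate grid must be nonempty")
    labels = np.asarray(assignments)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x, _ = allele_count_matrix(ds)

    def reassignment(scores: np.ndarray, lab: np.ndarray) -> float:
        lda = LinearDiscriminantAnalysis()
        lda.fit(scores, lab)
        pred = lda.predict(scores)
        per_cluster = [
            (pred[lab == c] == c).mean() for c in np.unique(lab)
        ]
        return float(np.mean(per_cluster))

    out = {}
    for n_pca in grid:
        n_pca = int(n_pca)
        if n_pca >= ds.n_individuals:
            continue
        scores = pca_scores(x, n_pca=n_pca)
        obs = reassignment(scores, labels)
        rand = np.mean(
            [reassignment(scores, rng.permutation(labels)) for _ in range(n_rand)]
        )
        out[n_pca] = obs - rand
    ascores = pd.Series(out, name="a_score")
    return int(ascores.idxmax()), ascores


def categorize_individuals(
    model: ClusterModel,
    threshold: float = 0.9,
    population_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Assigned-vs-admixed calls per individual and per-population patterns.

    An individual is *assigned* to a cluster when its maximum membership
    exceeds the threshold; otherwise it is *admixed*.  When ``population_of``
    maps individual id -> population, a per-population pattern table is also
    returned: ``single-cluster`` (every assigned member in one cluster) or
    ``mixed`` (assigned members from >= 2 clusters), with a
    ``contains_admixed`` flag in either case.
    """
    m = model.memberships
    max_mem = m.max(axis=1)
    best = m.idxmax(axis=1)
    per_ind = pd.DataFrame(
        {
            "cluster": best,
            "max_membership": max_mem,
            "status": np.where(max_mem > threshold, "assigned", "admixed"),
        },
        index=m.index,
    )
    patterns = None
    if population_of is not None:
        df = per_ind.copy()
        df["population_id"] = [population_of[i] for i in df.index]
        patterns = _population_patterns(df)
    return per_ind, patterns


def _population_patterns(per_ind: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pop, sub in per_ind.groupby("population_id", sort=False):
        assigned = sub[sub["status"] == "assigned"]
        clusters = set(assigned["cluster"])
        has_admixed = bool((sub["status"] == "admixed").any())
        if len(clusters) <= 1:
            pattern = "single-cluster"
        else:
            pattern = "mixed"
        rows.append(
            {
                "population_id": pop,
                "pattern": pattern,
                "n_clusters_present": len(clusters),
                "contains_admixed": has_admixed,
                "main_cluster": assigned["cluster"].mode().iat[0] if len(assigned) else None,
            }
        )
    return pd.DataFrame(rows).set_index("population_id")
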