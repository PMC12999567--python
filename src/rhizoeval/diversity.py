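"""Alpha/beta diversity: rarefaction, Simpson index, Bray-Curtis, PCoA,
PERMANOVA (Adonis-style) and the Wilcoxon rank-sum test.

The ordination and the group test both run on Bray-Curtis dissimilarities.
The Simpson index is reported in its dominance form D = sum(p_i^2) by
default (higher D = lower diversity); the complement 1 - D is available via
``form="complement"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .io import DistanceMatrix, FeatureTable, relative_abundance

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "rarefy",
    "simpson_index",
    "bray_curtis",
    "pcoa",
    "permanova",
    "wilcoxon_rank_sum",
]


def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> FeatureTable:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample total (the convention for
    removing library-size bias before diversity analyses).  A single draw
    is taken per sample with the recorded seed, so results are
    reproducible bit-for-bit.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    low = totals.index[totals < depth]
    if len(low):
        raise ValueError(
            f"sample {low[0]!r} has total {int(totals[low[0]])} < rarefaction depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        if totals[sid] == depth:
            out[sid] = col.copy()
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    return FeatureTable(
        pd.DataFrame(out, index=table.counts.index, dtype=np.int64)
    )


def simpson_index(table: FeatureTable, form: str = "dominance") -> pd.Series:
    """Per-sample Simpson index.

    ``dominance`` (default) returns D = sum(p_i^2) in (0, 1]; higher values
    mean a more dominated, less diverse community.  ``complement`` returns
    1 - D.
    """
    rel = relative_abundance(table)
    d = (rel**2).sum(axis=0)
    if form == "dominance":
        return d
    if form == "complement":
        return 1.0 - d
    raise ValueError(f"unknown Simpson form {form!r}")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples,
    BC(j,k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    d = squareform(pdist(table.counts.to_numpy(float).T, metric="braycurtis"))
    return DistanceMatrix(tuple(table.sample_ids), d)


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates on axes ordered by decreasing
    positive eigenvalue, with percent variation explained per axis."""

    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray    # positive eigenvalues, descending
    proportion_explained: np.ndarray  # percent, same length


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical principal coordinate analysis.

    Gower-centers -D^2/2, eigendecomposes, and keeps only positive
    eigenvalues: they define both the coordinates (eigenvectors scaled by
    sqrt(eigenvalue)) and the explained-variance denominator.
    """
    d = np.asarray(dm.values, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals).max()) if n else 0.0
    pos = evals > tol
    evals, evecs = evals[pos], evecs[:, pos]
    coords = evecs * np.sqrt(evals)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=100.0 * evals / evals.sum() if evals.size else evals,
    )


@dataclass
class PermanovaResult:
    f: float
    p: float
    n_perm: int
    n_ge: int  # permutations with F >= observed
    n_groups: int
    n_samples: int


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    # Anderson's one-way pseudo-F from squared distances:
    # SS_total = sum_{i<j} d2_ij / n ; SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        m = codes == g
        n_g = int(m.sum())
        sub = d2[np.ix_(m, m)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``grouping`` is a sequence of group labels aligned with ``dm.ids`` or a
    mapping id → label.  The p-value uses free permutation of the labels
    with the add-one estimator p = (1 + #{F_perm >= F_obs}) / (1 + n_perm),
    so p >= 1/(1+n_perm) always.
    """
    if isinstance(grouping, dict):
        grouping = [grouping[i] for i in dm.ids]
    labels = np.asarray(list(grouping))
    if len(labels) != len(dm.ids):
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError(
            f"group {uniq[int(np.argmin(sizes))]!r} has fewer than 2 samples"
        )
    d2 = dm.values**2
    f_obs = _permanova_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, len(uniq)) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return PermanovaResult(
        f=float(f_obs), p=float(p), n_perm=n_perm, n_ge=n_ge,
        n_groups=len(uniq), n_samples=len(labels),
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when n + m <= 12 and there are no ties; the normal
    approximation with tie correction otherwise.  Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
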