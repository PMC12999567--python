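"""Mantel association of community dissimilarity with environmental
factors, and the pairwise Spearman factor-correlation panel.

The environmental distance matrix is Euclidean distance on z-scored
factors (population standard deviation), the construction implied by the
vegan-ecosystem workflow the Mantel stage mirrors.  Mantel correlation is
the Spearman rank correlation of the two off-diagonal distance vectors;
its null distribution comes from simultaneous row/column permutation of
the second matrix, one-sided "greater" by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import DistanceMatrix

__all__ = [
    "MantelResult",
    "factor_distance",
    "mantel_test",
    "spearman_factor_matrix",
    "significance_stars",
]


def factor_distance(frame: pd.DataFrame, factors=None) -> DistanceMatrix:
    """Euclidean distance between samples on z-scored factors.

    ``frame`` is samples × factors.  Each selected factor is standardized
    to mean 0 and (population) SD 1, so the matrix is invariant to any
    positive affine rescaling of a factor's units.
    """
    x = frame[list(factors)] if factors is not None else frame
    if x.isna().any().any():
        raise ValueError("selected factors contain missing values")
    v = x.to_numpy(float)
    sd = v.std(axis=0)
    if (sd == 0).any():
        bad = x.columns[int(np.argmin(sd))]
        raise ValueError(f"factor {bad!r} has zero variance")
    z = (v - v.mean(axis=0)) / sd
    return DistanceMatrix(tuple(x.index), squareform(pdist(z, metric="euclidean")))


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    alternative: str


def _condensed(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    r is the ``method`` correlation of the n(n−1)/2 upper-triangle entries.
    The null permutes rows/columns of ``d2`` simultaneously; with
    ``n_perm="exact"`` all n! permutations are enumerated (n ≤ 8), else
    ``n_perm`` random permutations with the add-one estimator
    p = (1 + #extreme)/(1 + n_perm).  ``alternative`` is "greater"
    (the vegan default) or "two-sided".
    """
    if tuple(d1.ids) != tuple(d2.ids):
        raise ValueError("distance matrices have mismatched ids")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m1, m2 = d1.values, d2.values
    if method == "spearman":
        # rank-transform off-diagonals once; simultaneous permutation of d2
        # only reshuffles which entries pair up, never their ranks
        v1 = stats.rankdata(_condensed(m1))
        r2 = squareform(stats.rankdata(_condensed(m2)))
    elif method == "pearson":
        v1 = _condensed(m1)
        r2 = m2
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    def corr(perm_idx) -> float:
        v2 = _condensed(r2[np.ix_(perm_idx, perm_idx)])
        return float(np.corrcoef(v1, v2)[0, 1])

    identity = np.arange(n)
    r_obs = corr(identity)

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        return abs(r_perm) >= abs(r_obs) - 1e-12

    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if extreme(corr(np.array(perm))):
                count += 1
        return MantelResult(r=r_obs, p=count / total, n_perm=total,
                            method=method, alternative=alternative)

    rng = np.random.default_rng(seed)
    b = sum(extreme(corr(rng.permutation(n))) for _ in range(n_perm))
    return MantelResult(r=r_obs, p=(1 + b) / (1 + n_perm), n_perm=n_perm,
                        method=method, alternative=alternative)


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Null distribution of Spearman rho for untied samples of size n."""
    base = np.arange(n)
    perms = np.array(list(itertools.permutations(range(n))))
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def _spearman_p(rho: float, n: int, exact_ok: bool) -> float:
    if math.isnan(rho):
        return float("nan")
    if exact_ok and n <= 9:
        null = _exact_rho_null(n)
        return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_factor_matrix(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and two-sided p over factor columns.

    Exact permutation p for n ≤ 9 untied samples, the t approximation
    otherwise.  Zero-variance factors yield missing (NaN) entries, never 0.
    """
    if frame.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    cols = list(frame.columns)
    n = frame.shape[0]
    x = frame.to_numpy(float)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    sd = x.std(axis=0)
    for i, a in enumerate(cols):
        if sd[i] == 0:
            rho.loc[a, :] = np.nan
            rho.loc[:, a] = np.nan
            pval.loc[a, :] = np.nan
            pval.loc[:, a] = np.nan
    for i, a in enumerate(cols):
        if sd[i] == 0:
            continue
        for j in range(i + 1, len(cols)):
            bcol = cols[j]
            if sd[j] == 0:
                continue
            r = float(stats.spearmanr(x[:, i], x[:, j]).statistic)
            ties = (len(np.unique(x[:, i])) < n) or (len(np.unique(x[:, j])) < n)
            p = _spearman_p(r, n, exact_ok=not ties)
            rho.loc[a, bcol] = rho.loc[bcol, a] = r
            pval.loc[a, bcol] = pval.loc[bcol, a] = p
    return rho, pval


def significance_stars(p: float) -> str:
    """Conventional significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
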