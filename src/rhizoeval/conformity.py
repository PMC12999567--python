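"""Treatment comparison of indicators and the fuzzy membership-function
composite ("conformity") score.

Each indicator is min-max normalized over treatment MEANS into a membership
score in [0, 1] (reversed for cost-direction indicators, where lower is
better).  Indicator weights are each indicator's mean absolute pairwise
correlation with the other indicators, computed on replicate-level data and
normalized to sum 1.  The composite score per treatment is the weighted sum
of memberships; percent improvement is reported against the designated
control.  Group comparison of single indicators uses one-way ANOVA with
Tukey's HSD and a compact letter display ("a" = highest mean).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import IndicatorTable

__all__ = [
    "ConformityResult",
    "GroupComparison",
    "percent_change",
    "membership",
    "membership_matrix",
    "correlation_weights",
    "composite_score",
    "evaluate_conformity",
    "anova_tukey_cld",
]


def percent_change(treatment_mean: float, control_mean: float) -> float:
    """100·(treatment − control)/control, rounded to 1 d.p."""
    if control_mean == 0:
        raise ValueError("percent change undefined for a zero control mean")
    return round(100.0 * (treatment_mean - control_mean) / control_mean, 1)


def membership(values: pd.Series, direction: str = "benefit") -> pd.Series:
    """Linear min-max membership of per-treatment values.

    benefit: u = (x − min)/(max − min); cost: u = (max − x)/(max − min).
    A constant indicator (max == min) maps every treatment to 0.5.
    """
    if direction not in ("benefit", "cost"):
        raise ValueError(f"direction must be 'benefit' or 'cost', got {direction!r}")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return pd.Series(0.5, index=values.index)
    u = (values - lo) / (hi - lo)
    return 1.0 - u if direction == "cost" else u


def membership_matrix(tbl: IndicatorTable) -> pd.DataFrame:
    """Treatments × indicators matrix of membership scores over treatment
    means, using each indicator's direction flag; undirected indicators are
    excluded."""
    means = tbl.treatment_means()
    cols = {}
    for ind in tbl.scoring_indicators():
        cols[ind] = membership(means[ind], tbl.directions[ind])
    if not cols:
        raise ValueError("no indicators carry a benefit/cost direction")
    return pd.DataFrame(cols)


def correlation_weights(tbl: IndicatorTable, method: str = "pearson") -> pd.Series:
    """Indicator weights from mean absolute pairwise correlations.

    raw_i = mean_{j≠i} |r_ij| on replicate-level values; w = raw / sum(raw).
    """
    inds = tbl.scoring_indicators()
    if len(inds) < 2:
        raise ValueError("need at least 2 directed indicators for weighting")
    x = tbl.values[inds].to_numpy(float).T  # indicators × replicates
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = inds[int(np.argmin(sd))]
        raise ValueError(f"indicator {bad!r} has zero variance")
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.abs(np.corrcoef(x))
    np.fill_diagonal(r, 0.0)
    raw = r.sum(axis=1) / (len(inds) - 1)
    w = raw / raw.sum()
    return pd.Series(w, index=inds)


def composite_score(u: pd.DataFrame, w: pd.Series) -> pd.Series:
    """S_t = sum_i w_i · u_{t,i} for each treatment row of ``u``."""
    if u.isna().any().any():
        t = u.index[u.isna().any(axis=1)][0]
        raise ValueError(f"treatment {t!r} is missing an indicator value")
    missing = [i for i in u.columns if i not in w.index]
    if missing:
        raise ValueError(f"no weight for indicators {missing}")
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return (u * w[u.columns]).sum(axis=1)


@dataclass
class ConformityResult:
    weights: pd.Series            # per indicator, sums to 1
    membership: pd.DataFrame      # treatments × indicators, in [0, 1]
    scores: pd.Series             # composite score per treatment
    improvement_pct: pd.Series    # percent improvement vs. control
    control: str


def evaluate_conformity(
    tbl: IndicatorTable, control: str = "Ctrl", weight_method: str = "pearson"
) -> ConformityResult:
    """Full conformity evaluation of an indicator table."""
    if control not in tbl.treatments:
        raise ValueError(f"control treatment {control!r} not in table")
    w = correlation_weights(tbl, method=weight_method)
    u = membership_matrix(tbl)
    s = composite_score(u, w)
    if s[control] == 0:
        # control at the minimum of every indicator: relative improvement
        # is undefined, reported as missing
        imp = pd.Series(np.nan, index=s.index)
        imp[control] = 0.0
    else:
        imp = pd.Series(
            {t: percent_change(s[t], s[control]) for t in s.index}, index=s.index
        )
    return ConformityResult(weights=w, membership=u, scores=s,
                            improvement_pct=imp, control=control)


# ---------------------------------------------------------------------------
# ANOVA + Tukey + compact letter display


@dataclass
class GroupComparison:
    indicator: str
    means: pd.Series
    sds: pd.Series
    n: pd.Series
    f: float
    p: float
    tukey_p: pd.DataFrame      # symmetric matrix of adjusted pairwise p
    letters: dict              # treatment → letter string
    alpha: float
    degenerate: bool = False   # zero variance everywhere with unequal means


def _compact_letters(order: list, significant: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups by descending mean; ``significant`` holds
    frozensets {i, j} of significantly different pairs.  Groups sharing a
    letter are not significantly different.
    """
    cols: list[set] = [set(order)]
    for pair in significant:
        i, j = tuple(pair)
        for col in [c for c in cols if i in c and j in c]:
            cols.remove(col)
            for newcol in (col - {i}, col - {j}):
                if newcol and not any(newcol <= other for other in cols):
                    cols = [c for c in cols if not (c <= newcol)]
                    cols.append(newcol)
    # letter order follows the highest-mean member of each column
    cols.sort(key=lambda c: min(order.index(g) for g in c))
    letters: dict = {g: "" for g in order}
    for k, col in enumerate(cols):
        for g in col:
            letters[g] += string.ascii_lowercase[k]
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def anova_tukey_cld(
    tbl: IndicatorTable, indicator: str, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc and letter display.

    Letters follow the convention of field-trial tables: "a" marks the
    highest mean, and treatments sharing any letter do not differ at
    ``alpha``.  If the overall ANOVA is not significant all treatments
    share "a".  With zero within-group variance everywhere but unequal
    means the test is undefined; distinct letters are assigned and the
    result flagged degenerate.
    """
    if indicator not in tbl.indicators:
        raise ValueError(f"unknown indicator {indicator!r}")
    groups = tbl.replicate_values(indicator)
    treatments = list(groups)
    if len(treatments) < 2:
        raise ValueError("need at least 2 treatments")
    arrays = [groups[t] for t in treatments]
    means = pd.Series({t: g.mean() for t, g in groups.items()})
    sds = pd.Series({t: g.std(ddof=1) for t, g in groups.items()})
    ns = pd.Series({t: len(g) for t, g in groups.items()})
    order = list(means.sort_values(ascending=False, kind="stable").index)

    if all(g.std() == 0 for g in arrays):
        if means.nunique() > 1:
            tukey_p = pd.DataFrame(0.0, index=treatments, columns=treatments)
            letters = {t: string.ascii_lowercase[i] for i, t in enumerate(order)}
            return GroupComparison(indicator, means, sds, ns, float("inf"), 0.0,
                                   tukey_p, letters, alpha, degenerate=True)
        tukey_p = pd.DataFrame(1.0, index=treatments, columns=treatments)
        return GroupComparison(indicator, means, sds, ns, 0.0, 1.0, tukey_p,
                               {t: "a" for t in treatments}, alpha)

    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    tukey_p = pd.DataFrame(hsd.pvalue, index=treatments, columns=treatments)
    if p >= alpha:
        letters = {t: "a" for t in treatments}
    else:
        significant = {
            frozenset((a, b))
            for ia, a in enumerate(treatments)
            for b in treatments[ia + 1:]
            if tukey_p.loc[a, b] < alpha
        }
        letters = _compact_letters(order, significant)
    return GroupComparison(indicator, means, sds, ns, float(f), float(p),
                           tukey_p, letters, alpha)
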