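"""Thresholded co-occurrence networks and their topology.

Per treatment group, taxa passing a prevalence filter (computed on ALL
samples) are correlated on relative abundances; taxon pairs with
|r| > 0.80 and p < 0.05 (both strict) become signed, weighted undirected
edges.  Topology metrics follow the Gephi conventions: average path length
over connected pairs only, Louvain modularity (best of 10 seeded restarts),
mean local clustering, and a network-level eigenvector-centrality aggregate
(mean node centrality, power method on the largest component, L2
normalized).  Robustness is measured as the giant-component survival curve
under uniform random node removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, relative_abundance

__all__ = [
    "NetworkParams",
    "TopologySummary",
    "RobustnessResult",
    "prevalence_filter",
    "correlation_matrix",
    "pvalue_from_r",
    "build_network",
    "topology",
    "sign_proportions",
    "robustness",
]


@dataclass
class NetworkParams:
    prevalence: float = 0.5       # strict fraction-of-samples threshold
    r_threshold: float = 0.80     # on |r|, strict
    alpha: float = 0.05           # on p, strict
    method: str = "pearson"       # or "spearman"
    scope: str = "per_treatment"  # or "pooled"

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence threshold must lie in (0, 1)")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def prevalence_filter(table: FeatureTable, threshold: float = 0.5) -> FeatureTable:
    """Keep taxa with nonzero counts in strictly more than
    ``threshold``·n_samples samples (a taxon in exactly half the samples is
    dropped)."""
    present = (table.counts > 0).sum(axis=1)
    keep = present > threshold * table.shape[1]
    return FeatureTable(table.counts.loc[keep].copy())


def pvalue_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation coefficient via the t transform
    t = r·sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def correlation_matrix(
    table: FeatureTable, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxon × taxon correlation (R) and significance (P) matrices.

    Computed on relative abundances.  A zero-variance taxon has undefined
    correlations: its rows/columns are NaN (missing), never 0.
    """
    if table.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = relative_abundance(table).to_numpy()
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = x.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    p = pvalue_from_r(r, n=table.shape[1])
    np.fill_diagonal(p, np.where(bad, np.nan, 0.0))
    idx = pd.Index(table.taxon_ids)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def build_network(
    R: pd.DataFrame,
    P: pd.DataFrame,
    params: NetworkParams | None = None,
    node_attrs: dict | None = None,
) -> nx.Graph:
    """Signed undirected graph with an edge wherever |r| > r_threshold AND
    p < alpha (strict).  All taxa of R remain as nodes, so isolated taxa
    that passed the prevalence filter are kept.  Missing (NaN)
    correlations never create edges."""
    params = params or NetworkParams()
    if R.shape != P.shape or list(R.index) != list(P.index):
        raise ValueError("R and P must be conformable with identical ids")
    g = nx.Graph()
    for t in R.index:
        g.add_node(t, **(node_attrs.get(t, {}) if node_attrs else {}))
    rv, pv = R.to_numpy(), P.to_numpy()
    n = len(R.index)
    iu, ju = np.triu_indices(n, k=1)
    ok = (
        np.isfinite(rv[iu, ju])
        & np.isfinite(pv[iu, ju])
        & (np.abs(rv[iu, ju]) > params.r_threshold)
        & (pv[iu, ju] < params.alpha)
    )
    for i, j in zip(iu[ok], ju[ok]):
        r = float(rv[i, j])
        g.add_edge(
            R.index[i], R.index[j],
            r=r, p=float(pv[i, j]), sign=1 if r > 0 else -1, weight=abs(r),
        )
    g.graph.update(
        r_threshold=params.r_threshold, alpha=params.alpha, method=params.method
    )
    return g


@dataclass
class TopologySummary:
    """Network-level metrics in the conventional report order."""

    edges: int
    nodes: int
    average_degree: float
    average_path_length: float | None
    modularity: float
    average_clustering: float
    eigenvector_centrality: float
    positive_pct: float | None
    negative_pct: float | None

    COLUMNS = (
        "edges", "nodes", "average_degree", "average_path_length",
        "modularity", "average_clustering", "eigenvector_centrality",
        "positive_pct", "negative_pct",
    )

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


def _average_path_length(g: nx.Graph) -> float | None:
    # mean shortest-path length over connected node pairs only
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += len(comp) * (len(comp) - 1)
    if pairs == 0:
        return None
    return total / pairs


def _modularity(g: nx.Graph, seed: int, restarts: int = 10) -> float:
    if g.number_of_edges() == 0:
        return 0.0
    best = -np.inf
    for k in range(restarts):
        parts = nx.community.louvain_communities(g, weight=None, resolution=1.0, seed=seed + k)
        q = nx.community.modularity(g, parts, weight=None, resolution=1.0)
        best = max(best, q)
    return float(best)


def _eigenvector_aggregate(g: nx.Graph) -> float:
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        return 0.0
    lcc = max(nx.connected_components(g), key=len)
    if len(lcc) < 2:
        return 0.0
    # deterministic power iteration on the largest component's adjacency
    a = nx.to_numpy_array(g.subgraph(lcc), weight=None)
    v = np.full(a.shape[0], 1.0 / np.sqrt(a.shape[0]))
    for _ in range(1000):
        nxt = a @ v
        nxt += v * 1e-9  # tiny shift keeps bipartite cases converging
        nxt /= np.linalg.norm(nxt)
        if np.linalg.norm(nxt - v) < 1e-12:
            v = nxt
            break
        v = nxt
    v = np.abs(v) / np.linalg.norm(np.abs(v))
    # nodes outside the largest component contribute 0 to the mean
    return float(v.sum() / g.number_of_nodes())


def sign_proportions(g: nx.Graph) -> tuple[float, float]:
    """Percent positive / negative edges, rounded to 2 d.p. with the
    rounding remainder assigned to the larger class so they sum to 100."""
    e = g.number_of_edges()
    if e == 0:
        raise ValueError("sign proportions undefined for an edgeless graph")
    pos = sum(1 for _, _, d in g.edges(data=True) if d["sign"] > 0)
    neg = e - pos
    pos_pct = round(100.0 * pos / e, 2)
    neg_pct = round(100.0 * neg / e, 2)
    rem = round(100.0 - pos_pct - neg_pct, 2)
    if rem:
        if pos >= neg:
            pos_pct = round(pos_pct + rem, 2)
        else:
            neg_pct = round(neg_pct + rem, 2)
    return pos_pct, neg_pct


def topology(g: nx.Graph, seed: int = 0) -> TopologySummary:
    """Topology metrics for one network.  For an empty/edgeless graph the
    undefined metrics are reported as 0 (path length and edge-sign
    percentages as missing)."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 1:
        raise ValueError("topology needs at least 1 node")
    pos_pct = neg_pct = None
    if e > 0:
        pos_pct, neg_pct = sign_proportions(g)
    return TopologySummary(
        edges=e,
        nodes=n,
        average_degree=2.0 * e / n,
        average_path_length=_average_path_length(g),
        modularity=_modularity(g, seed=seed),
        average_clustering=float(np.mean(list(nx.clustering(g).values()))) if n else 0.0,
        eigenvector_centrality=_eigenvector_aggregate(g),
        positive_pct=pos_pct,
        negative_pct=neg_pct,
    )


@dataclass
class RobustnessResult:
    fractions: np.ndarray
    mean_giant_fraction: np.ndarray  # relative to the ORIGINAL node count
    auc: float
    n_rep: int
    seed: int


def robustness(
    g: nx.Graph,
    fractions: np.ndarray | None = None,
    n_rep: int = 100,
    seed: int = 0,
) -> RobustnessResult:
    """Giant-component survival under uniform random node removal.

    For each removal fraction f, ``floor(f·N)`` nodes are deleted uniformly
    at random and the largest-component size relative to the original N is
    recorded; curves are averaged over ``n_rep`` repetitions.  AUC is the
    trapezoid integral normalized by the fraction span, so it lies in
    [0, 1].
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("robustness needs at least 2 nodes")
    if fractions is None:
        fractions = np.arange(0.0, 0.5001, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    nodes = list(g.nodes)
    rng = np.random.default_rng(seed)
    base = max(len(c) for c in nx.connected_components(g)) / n
    means = np.empty(len(fractions))
    for fi, f in enumerate(fractions):
        k = int(np.floor(f * n))
        if k == 0:
            means[fi] = base
            continue
        acc = 0.0
        for _ in range(n_rep):
            drop = rng.choice(n, size=k, replace=False)
            keep = [nodes[i] for i in range(n) if i not in set(drop.tolist())]
            sub = g.subgraph(keep)
            giant = max((len(c) for c in nx.connected_components(sub)), default=0)
            acc += giant / n
        means[fi] = acc / n_rep
    auc = float(np.trapezoid(means, fractions) / (fractions[-1] - fractions[0]))
    return RobustnessResult(fractions=fractions, mean_giant_fraction=means,
                            auc=auc, n_rep=n_rep, seed=seed)
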