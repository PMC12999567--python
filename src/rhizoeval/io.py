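"""Shared data model and tabular/graph I/O.

All on-disk formats are plain UTF-8, tab-delimited text with "." as the
decimal separator:

* feature table  — header ``taxon_id\\t<sample1>\\t...``, integer counts,
  taxa as rows, samples as columns;
* taxonomy       — ``taxon_id\\tlineage`` with ";"-separated ranks,
  optional QIIME-style prefixes (``g__``) stripped on parse;
* metadata       — ``sample_id\\ttreatment\\treplicate``;
* indicator table— ``treatment\\treplicate\\t<indicator...>`` plus a sidecar
  direction file ``indicator\\tdirection``;
* distance matrix— square TSV with the id list as header row and column;
* networks       — edge-list TSV (``source target r p sign``) or GraphML.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "RESERVED_LABELS",
    "FeatureTable",
    "TaxonomyMap",
    "SampleMetadata",
    "IndicatorTable",
    "DistanceMatrix",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_indicator_table",
    "write_indicator_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "relative_abundance",
    "aggregate_taxa",
    "write_network",
    "read_network",
]

#: Lineage ranks, coarse to fine.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Labels produced by :func:`aggregate_taxa`; input taxa may not use them.
RESERVED_LABELS = frozenset({"Others", "Unclassified"})

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Taxa × samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by taxon id, columns by sample id, integer dtype.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(list(df.index), "taxon")
        _check_unique(list(df.columns), "sample")
        bad = RESERVED_LABELS.intersection(df.index)
        if bad:
            raise ValueError(
                f"taxon ids {sorted(bad)} collide with reserved labels"
            )
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValueError("feature table counts must be integers")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            arr = df.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.counts.copy())


@dataclass
class TaxonomyMap:
    """taxon id → ranked lineage (coarse→fine); missing ranks are ``None``."""

    lineages: dict[str, tuple]

    def rank_label(self, taxon_id: str, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lineage = self.lineages.get(taxon_id)
        if lineage is None:
            return None
        idx = RANKS.index(rank)
        if idx >= len(lineage):
            return None
        label = lineage[idx]
        return label if label else None


@dataclass
class SampleMetadata:
    """sample id → (treatment, replicate index).

    Replicate indices must be unique within a treatment.
    """

    frame: pd.DataFrame  # index sample_id; columns treatment, replicate

    def __post_init__(self) -> None:
        _check_unique(list(self.frame.index), "sample")
        for col in ("treatment", "replicate"):
            if col not in self.frame.columns:
                raise ValueError(f"metadata missing column {col!r}")
        dup = self.frame.duplicated(subset=["treatment", "replicate"])
        if dup.any():
            sid = self.frame.index[dup][0]
            raise ValueError(
                f"duplicate replicate index within treatment (sample {sid!r})"
            )

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.frame["treatment"]:
            seen.setdefault(t, None)
        return list(seen)

    def grouping(self, sample_ids: Sequence[str]) -> list[str]:
        """Treatment label for each requested sample, in order."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        return [self.frame.loc[s, "treatment"] for s in sample_ids]


@dataclass
class IndicatorTable:
    """Replicate-level numeric indicators with per-indicator directions.

    ``values`` holds one row per (treatment, replicate) with numeric
    indicator columns.  ``directions`` maps indicator → ``"benefit"``,
    ``"cost"`` or ``None`` (excluded from composite scoring).
    """

    values: pd.DataFrame
    directions: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("treatment", "replicate"):
            if col not in self.values.columns:
                raise ValueError(f"indicator table missing column {col!r}")
        for ind, d in self.directions.items():
            if d not in ("benefit", "cost", None):
                raise ValueError(f"direction for {ind!r} must be benefit/cost/None")
        counts = self.values.groupby("treatment").size()
        if (counts < 2).any():
            t = counts.index[counts < 2][0]
            raise ValueError(f"treatment {t!r} has fewer than 2 replicates")
        for ind in self.scoring_indicators():
            if self.values[ind].isna().any():
                raise ValueError(f"missing values in scored indicator {ind!r}")

    @property
    def indicators(self) -> list[str]:
        return [c for c in self.values.columns if c not in ("treatment", "replicate")]

    def scoring_indicators(self) -> list[str]:
        """Indicators carrying a benefit/cost direction."""
        return [i for i in self.indicators if self.directions.get(i) in ("benefit", "cost")]

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.values["treatment"]:
            seen.setdefault(t, None)
        return list(seen)

    def treatment_means(self) -> pd.DataFrame:
        """Treatment × indicator matrix of means, treatments in table order."""
        m = self.values.groupby("treatment", sort=False)[self.indicators].mean()
        return m.loc[self.treatments]

    def replicate_values(self, indicator: str) -> dict[str, np.ndarray]:
        out = {}
        for t in self.treatments:
            out[t] = self.values.loc[self.values["treatment"] == t, indicator].to_numpy(float)
        return out

    def sample_frame(self) -> pd.DataFrame:
        """Indicator values indexed by ``<treatment>_r<replicate>`` sample ids."""
        idx = [
            f"{t}_r{int(r)}"
            for t, r in zip(self.values["treatment"], self.values["replicate"])
        ]
        out = self.values[self.indicators].copy()
        out.index = idx
        return out


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        object.__setattr__(self, "ids", ids)
        _check_unique(ids, "distance-matrix")
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if d.size and d.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        object.__setattr__(self, "values", d)

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(path) -> FeatureTable:
    """Read a taxa × samples TSV of integer counts.

    Raises :class:`ValueError` naming the offending id or cell on duplicate
    ids and on negative or non-numeric counts.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: feature table needs at least one sample column")
    _check_unique(header[1:], "sample")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    _check_unique(list(df.index), "taxon")
    parsed = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            taxon = df.index[vals.isna()][0]
            raise ValueError(
                f"{path}: non-numeric count at taxon {taxon!r}, sample {col!r}"
            )
        frac = vals != np.floor(vals)
        if frac.any():
            taxon = df.index[frac.to_numpy()][0]
            raise ValueError(
                f"{path}: non-integer count at taxon {taxon!r}, sample {col!r}"
            )
        if (vals < 0).any():
            taxon = df.index[(vals < 0).to_numpy()][0]
            raise ValueError(
                f"{path}: negative count at taxon {taxon!r}, sample {col!r}"
            )
        parsed[col] = vals.astype(np.int64)
    out = pd.DataFrame(parsed, index=df.index)
    out.index.name = "taxon_id"
    return FeatureTable(out)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def _parse_lineage(text: str) -> tuple:
    parts = [
        _RANK_PREFIX.sub("", p.strip()) or None for p in text.split(";")
    ]
    while parts and parts[-1] is None:
        parts.pop()
    return tuple(parts)


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["taxon_id", "lineage"]:
        raise ValueError(f"{path}: expected header 'taxon_id\\tlineage'")
    _check_unique(list(df["taxon_id"]), "taxon")
    return TaxonomyMap(
        {t: _parse_lineage(l) for t, l in zip(df["taxon_id"], df["lineage"])}
    )


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("taxon_id\tlineage\n")
        for t, lineage in tax.lineages.items():
            fh.write(f"{t}\t{';'.join('' if p is None else p for p in lineage)}\n")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: expected a 'sample_id' column")
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(int)
    return SampleMetadata(df[["treatment", "replicate"]])


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_indicator_table(path, directions_path=None) -> IndicatorTable:
    df = pd.read_csv(path, sep="\t", dtype={"treatment": str})
    directions: dict[str, str | None] = {}
    if directions_path is not None:
        dd = pd.read_csv(directions_path, sep="\t", dtype=str, keep_default_na=False)
        if list(dd.columns[:2]) != ["indicator", "direction"]:
            raise ValueError(
                f"{directions_path}: expected header 'indicator\\tdirection'"
            )
        for ind, d in zip(dd["indicator"], dd["direction"]):
            directions[ind] = d if d in ("benefit", "cost") else None
    return IndicatorTable(df, directions)


def write_indicator_table(tbl: IndicatorTable, path, directions_path=None) -> None:
    tbl.values.to_csv(path, sep="\t", index=False, lineterminator="\n")
    if directions_path is not None:
        with Path(directions_path).open("w", encoding="utf-8") as fh:
            fh.write("indicator\tdirection\n")
            for ind in tbl.indicators:
                d = tbl.directions.get(ind)
                fh.write(f"{ind}\t{d if d else 'none'}\n")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids differ")
    return DistanceMatrix(tuple(df.index), df.to_numpy(float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.values, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# transformations


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1 within 1e-12."""
    totals = table.sample_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    return table.counts.astype(float) / totals


def aggregate_taxa(
    table: FeatureTable, tax: TaxonomyMap, rank: str, top_k: int = 15
) -> FeatureTable:
    """Collapse taxa to ``rank``, keep the ``top_k`` most abundant labels.

    Counts are summed within identical rank labels; taxa without an
    annotation at ``rank`` are pooled as ``"Unclassified"``.  Output is
    restricted to the ``top_k`` labels by mean relative abundance across
    samples, with one trailing ``"Others"`` row holding the remainder so
    per-sample totals are conserved exactly.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    labels = [tax.rank_label(t, rank) or "Unclassified" for t in table.taxon_ids]
    grouped = table.counts.groupby(pd.Index(labels, name="taxon_id"), sort=False).sum()
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(f"sample {totals.index[totals == 0][0]!r} has zero total count")
    rel = grouped.astype(float) / totals
    order = list(rel.mean(axis=1).sort_values(ascending=False, kind="stable").index)
    kept = order[:top_k]
    rest = order[top_k:]
    out = grouped.loc[kept]
    if rest:
        others = grouped.loc[rest].sum(axis=0).to_frame("Others").T
        others.index.name = "taxon_id"
        out = pd.concat([out, others])
    # bypass the reserved-label guard: these labels are ours by construction
    ft = FeatureTable.__new__(FeatureTable)
    object.__setattr__(ft, "counts", out.astype(np.int64))
    return ft


# ---------------------------------------------------------------------------
# networks


def write_network(graph: nx.Graph, path, format: str = "edgelist_tsv") -> None:
    """Write a correlation network as an edge-list TSV or GraphML.

    The edge list carries ``source target r p sign``; GraphML carries the
    same quantities as edge attributes plus any node attributes.
    """
    path = Path(path)
    if format == "edgelist_tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tr\tp\tsign\n")
            for u, v, d in graph.edges(data=True):
                fh.write(
                    f"{u}\t{v}\t{d['r']:.6g}\t{d['p']:.6g}\t{int(d['sign'])}\n"
                )
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    if format == "edgelist_tsv":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            g.add_edge(
                str(row.source), str(row.target),
                r=float(row.r), p=float(row.p), sign=int(row.sign),
            )
        return g
    raise ValueError(f"unknown network format {format!r}")
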