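"""Synthetic study generator.

Emulates a four-treatment (control, basal application BA, foliar spray FS,
combined BA-FS) × five-replicate rhizosphere amplicon study of a biocontrol
Streptomyces trial: two marker-gene communities (bacterial 16S-like and
fungal ITS-like), each with a single dominant genus, treatment-driven
compositional shifts, replicate-level overdispersion, uneven sequencing
depths, plus replicate-level soil and leaf indicator tables.

The community model draws per-treatment compositions from a shared
log-normal base perturbed by treatment-specific multiplicative effects, and
per-sample counts from a Dirichlet-multinomial (the Dirichlet concentration
is the replicate-dispersion knob).  The fungal dominant genus is a
pathogen analog whose share is reduced multiplicatively under treatments;
the bacterial dominant genus increases under treatments.

All randomness flows through numpy's PCG64 generator; a fixed seed yields
bit-identical output on any platform.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    FeatureTable,
    IndicatorTable,
    SampleMetadata,
    TaxonomyMap,
    write_feature_table,
    write_indicator_table,
    write_metadata,
    write_taxonomy,
)

__all__ = [
    "StudyDesign",
    "CommunityModel",
    "IndicatorModel",
    "TABLE1_SOIL_INDICATORS",
    "SYNTHETIC_LEAF_INDICATORS",
    "default_fungal_model",
    "default_bacterial_model",
    "default_indicator_model",
    "generate_counts",
    "generate_taxonomy",
    "generate_indicators",
    "generate_study",
    "stage_seed",
]


def stage_seed(seed: int, key: int) -> int:
    """Deterministic 31-bit sub-seed derived via numpy's SeedSequence."""
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class StudyDesign:
    """Experimental layout and sequencing-depth model.

    Five replicates per treatment and a lognormal per-sample depth
    (median ``depth_median`` reads, log-sd ``depth_sigma``) so the
    rarefaction step is exercised by default.
    """

    treatments: tuple = ("Ctrl", "BA", "FS", "BA-FS")
    replicates: int = 5
    depth_median: int = 20_000
    depth_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per treatment")
        if self.depth_median <= 0:
            raise ValueError("sequencing depth must be positive")

    @property
    def control(self) -> str:
        return self.treatments[0]


@dataclass
class CommunityModel:
    """Composition model for one marker-gene community.

    dominant_share is the control-group expected share of the dominant
    genus; dominant_factors multiply it per treatment.  Non-dominant taxa
    get log-normal base abundances (sigma ``base_sigma``) and, per non-control
    treatment, a random ``affected_fraction`` of them is multiplied by
    exp(N(0, effect_sigma)) — the treatment effect driving beta-diversity
    separation.  ``overdispersion`` is the Dirichlet concentration of the
    replicate-level compositional noise (``None`` disables it).
    """

    n_taxa: int = 160
    dominant_share: float = 0.60
    dominant_factors: dict = field(
        default_factory=lambda: {"BA": 0.94, "FS": 0.96, "BA-FS": 0.88}
    )
    base_sigma: float = 1.5
    effect_sigma: float = 1.0
    affected_fraction: float = 0.30
    overdispersion: float | None = 300.0
    prefix: str = "fASV"
    kingdom: str = "Fungi"
    dominant_genus: str = "Fusarium_analog"

    def __post_init__(self) -> None:
        if not 0 < self.dominant_share < 1:
            raise ValueError("dominant_share must lie in (0, 1)")
        if any(f <= 0 for f in self.dominant_factors.values()):
            raise ValueError("dominant factors must be positive")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")


def default_fungal_model() -> CommunityModel:
    """Fungal ITS community: pathogen-analog genus at ~60% of control reads
    (within the 55.4–65.0% dominant-genus window), reduced multiplicatively
    under treatments (strongest, ×0.88, in the combined treatment)."""
    return CommunityModel()


def default_bacterial_model() -> CommunityModel:
    """Bacterial 16S community: dominant genus near 30% in controls (within
    the 28.4–38.5% window) and enriched under treatments."""
    return CommunityModel(
        n_taxa=320,
        dominant_share=0.29,
        dominant_factors={"BA": 1.15, "FS": 1.10, "BA-FS": 1.30},
        prefix="bASV",
        kingdom="Bacteria",
        dominant_genus="Luteitalea_analog",
    )


# Per-treatment (mean, SD) of soil physicochemical indicators, n = 5
# replicates; control first.  Units in the key.  All nutrient contents are
# benefit-direction for conformity scoring; pH carries no direction.
TABLE1_SOIL_INDICATORS: dict = {
    "pH": {
        "unit": "", "direction": None,
        "Ctrl": (7.73, 0.21), "BA": (7.79, 0.12), "FS": (7.78, 0.29), "BA-FS": (7.82, 0.23),
    },
    "organic_matter": {
        "unit": "g/kg", "direction": "benefit",
        "Ctrl": (16.92, 2.73), "BA": (19.06, 0.83), "FS": (18.90, 2.59), "BA-FS": (19.66, 0.80),
    },
    "hydrolyzable_N": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (69.20, 4.44), "BA": (80.00, 4.64), "FS": (70.40, 4.51), "BA-FS": (81.80, 2.17),
    },
    "available_P": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (16.34, 6.45), "BA": (25.66, 1.61), "FS": (30.80, 9.92), "BA-FS": (36.98, 16.73),
    },
    "available_K": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (500.80, 84.66), "BA": (415.60, 123.68), "FS": (438.60, 214.15), "BA-FS": (423.60, 77.09),
    },
    "available_Zn": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (1.25, 0.05), "BA": (1.28, 0.08), "FS": (1.26, 0.05), "BA-FS": (1.29, 0.06),
    },
    "available_Mn": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (4.80, 0.16), "BA": (5.36, 0.36), "FS": (5.02, 0.33), "BA-FS": (5.42, 0.39),
    },
    "available_Fe": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (2.74, 0.09), "BA": (3.08, 0.22), "FS": (2.92, 0.31), "BA-FS": (3.12, 0.07),
    },
    "available_Cu": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (0.81, 0.23), "BA": (1.36, 0.18), "FS": (1.48, 0.25), "BA-FS": (1.60, 0.16),
    },
    "exchangeable_Ca": {
        "unit": "mg/kg", "direction": "benefit",
        "Ctrl": (2033.60, 40.43), "BA": (2381.40, 64.76), "FS": (2246.00, 53.56), "BA-FS": (2467.00, 94.81),
    },
}

# Synthetic leaf yield/quality indicators.  The replicate-level leaf tables
# of the source field trial are not published; these stand-in parameters
# encode the reported qualitative pattern (highest yield and K content and
# lowest low-grade proportion, starch and sugars under the combined
# treatment) with plausible magnitudes.  Lower is better for the proportion
# of low-grade leaves, starch and total sugars.
SYNTHETIC_LEAF_INDICATORS: dict = {
    "leaf_yield": {
        "unit": "kg/ha", "direction": "benefit",
        "Ctrl": (2100.0, 110.0), "BA": (2352.0, 120.0), "FS": (2268.0, 115.0), "BA-FS": (2671.0, 130.0),
    },
    "low_grade_leaf_prop": {
        "unit": "%", "direction": "cost",
        "Ctrl": (18.0, 1.4), "BA": (15.3, 1.2), "FS": (16.2, 1.3), "BA-FS": (12.9, 1.1),
    },
    "leaf_K": {
        "unit": "%", "direction": "benefit",
        "Ctrl": (1.90, 0.12), "BA": (2.22, 0.13), "FS": (2.25, 0.13), "BA-FS": (2.31, 0.14),
    },
    "leaf_total_alkaloids": {
        "unit": "%", "direction": "benefit",
        "Ctrl": (2.42, 0.18), "BA": (4.04, 0.30), "FS": (2.60, 0.20), "BA-FS": (3.40, 0.25),
    },
    "leaf_starch": {
        "unit": "%", "direction": "cost",
        "Ctrl": (5.50, 0.40), "BA": (5.00, 0.35), "FS": (5.20, 0.38), "BA-FS": (4.60, 0.33),
    },
    "leaf_total_sugars": {
        "unit": "%", "direction": "cost",
        "Ctrl": (28.0, 1.5), "BA": (26.5, 1.4), "FS": (27.0, 1.4), "BA-FS": (25.0, 1.3),
    },
}


@dataclass
class IndicatorModel:
    """Per-treatment Normal(mean, SD) model for each indicator.

    ``params[indicator][treatment] = (mean, sd)``; draws for concentration
    indicators are truncated at zero.
    """

    params: dict
    directions: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, by_treat in self.params.items():
            for t, (_, sd) in by_treat.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {ind!r} in {t!r}")


def _indicator_model_from_spec(spec: dict) -> IndicatorModel:
    params, directions, units = {}, {}, {}
    for ind, row in spec.items():
        params[ind] = {t: v for t, v in row.items() if t not in ("unit", "direction")}
        directions[ind] = row["direction"]
        units[ind] = row["unit"]
    return IndicatorModel(params, directions, units)


def default_indicator_model(include_leaf: bool = True) -> IndicatorModel:
    spec = dict(TABLE1_SOIL_INDICATORS)
    if include_leaf:
        spec.update(SYNTHETIC_LEAF_INDICATORS)
    return _indicator_model_from_spec(spec)


# ---------------------------------------------------------------------------


def _compositions(design: StudyDesign, model: CommunityModel, rng) -> dict:
    """Expected composition vector per treatment (dominant taxon first)."""
    n_rest = model.n_taxa - 1
    base = rng.lognormal(0.0, model.base_sigma, n_rest)
    base /= base.sum()
    comps = {}
    for t in design.treatments:
        share = model.dominant_share * model.dominant_factors.get(t, 1.0)
        if share >= 1.0:
            raise ValueError(
                f"dominant share {share:.3f} for treatment {t!r} is infeasible (>= 1)"
            )
        effect = np.ones(n_rest)
        if t != design.control and model.effect_sigma > 0 and model.affected_fraction > 0:
            k = max(1, round(model.affected_fraction * n_rest))
            idx = rng.choice(n_rest, size=k, replace=False)
            effect[idx] = rng.lognormal(0.0, model.effect_sigma, k)
        rest = base * effect
        rest *= (1.0 - share) / rest.sum()
        comps[t] = np.concatenate([[share], rest])
    return comps


def generate_counts(
    design: StudyDesign, model: CommunityModel, seed: int | None = None
) -> tuple[FeatureTable, SampleMetadata]:
    """Draw a feature table and matching metadata for one community.

    Per sample: composition = Dirichlet(overdispersion × treatment
    composition) (skipped when overdispersion is None), depth ~ lognormal,
    counts ~ multinomial.  Deterministic given the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    comps = _compositions(design, model, rng)
    taxa = [f"{model.prefix}_{i:04d}" for i in range(model.n_taxa)]
    cols, sample_ids, meta_rows = {}, [], []
    for t in design.treatments:
        for r in range(1, design.replicates + 1):
            sid = f"{t}_r{r}"
            p = comps[t]
            if model.overdispersion is not None:
                q = rng.dirichlet(p * model.overdispersion)
                # dirichlet can return exact zeros for tiny alphas; multinomial copes
            else:
                q = p
            depth = max(1, int(round(rng.lognormal(np.log(design.depth_median), design.depth_sigma))))
            cols[sid] = rng.multinomial(depth, q / q.sum())
            sample_ids.append(sid)
            meta_rows.append((sid, t, r))
    counts = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon_id"), dtype=np.int64)
    meta = pd.DataFrame(
        {"treatment": [m[1] for m in meta_rows], "replicate": [m[2] for m in meta_rows]},
        index=pd.Index([m[0] for m in meta_rows], name="sample_id"),
    )
    return FeatureTable(counts), SampleMetadata(meta)


_PHYLA = {
    "Bacteria": ("Pseudomonadota", "Acidobacteriota", "Actinomycetota",
                 "Gemmatimonadota", "Chloroflexota", "Nitrospirota"),
    "Fungi": ("Ascomycota", "Basidiomycota", "Mortierellomycota",
              "Chytridiomycota", "Olpidiomycota"),
}


def generate_taxonomy(model: CommunityModel, seed: int = 0) -> TaxonomyMap:
    """Plausible ranked lineages; taxon 0 carries the dominant (for the
    fungal model: pathogen-analog) genus, remaining taxa are grouped three
    ASVs per genus so genus-level aggregation is non-trivial."""
    rng = np.random.default_rng(seed)
    phyla = _PHYLA.get(model.kingdom, _PHYLA["Bacteria"])
    lineages = {}
    for i in range(model.n_taxa):
        tid = f"{model.prefix}_{i:04d}"
        if i == 0:
            genus = model.dominant_genus
        else:
            genus = f"{model.prefix}_genus_{1 + (i - 1) // 3:03d}"
        phylum = phyla[int(rng.integers(len(phyla)))]
        lineages[tid] = (
            model.kingdom, phylum, f"{phylum}_class", f"{phylum}_order",
            f"{genus}_family", genus, f"{genus}_sp{i % 3 + 1}",
        )
    return TaxonomyMap(lineages)


def generate_indicators(
    design: StudyDesign, model: IndicatorModel, seed: int | None = None
) -> IndicatorTable:
    """Replicate indicator values ~ Normal(mean, SD), truncated at zero."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows: dict = {
        "treatment": [], "replicate": [],
        **{ind: [] for ind in model.params},
    }
    for t in design.treatments:
        for ind, by_treat in model.params.items():
            if t not in by_treat:
                raise ValueError(f"indicator {ind!r} has no parameters for treatment {t!r}")
        for r in range(1, design.replicates + 1):
            rows["treatment"].append(t)
            rows["replicate"].append(r)
        for ind, by_treat in model.params.items():
            mean, sd = by_treat[t]
            draws = rng.normal(mean, sd, design.replicates)
            for _ in range(100):  # redraw negatives (concentrations are >= 0)
                neg = draws < 0
                if not neg.any():
                    break
                draws[neg] = rng.normal(mean, sd, int(neg.sum()))
            rows[ind].extend(np.clip(draws, 0.0, None))
    return IndicatorTable(pd.DataFrame(rows), dict(model.directions))


def generate_study(
    design: StudyDesign,
    bacteria: CommunityModel | None = None,
    fungi: CommunityModel | None = None,
    indicators: IndicatorModel | None = None,
    outdir=None,
    force: bool = False,
) -> dict:
    """Write a complete synthetic study bundle and return its manifest.

    Files: bacteria/fungi feature tables and taxonomies, sample metadata,
    indicator table with direction sidecar, and ``manifest.yaml`` recording
    the seed and every model parameter.  Refuses to write into an existing
    non-empty directory unless ``force``.
    """
    if outdir is None:
        raise ValueError("outdir is required")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    bacteria = bacteria if bacteria is not None else default_bacterial_model()
    fungi = fungi if fungi is not None else default_fungal_model()
    indicators = indicators if indicators is not None else default_indicator_model()

    seeds = {
        "bacteria": stage_seed(design.seed, 1),
        "fungi": stage_seed(design.seed, 2),
        "indicators": stage_seed(design.seed, 3),
    }
    bt, meta = generate_counts(design, bacteria, seed=seeds["bacteria"])
    ft, _ = generate_counts(design, fungi, seed=seeds["fungi"])
    ind = generate_indicators(design, indicators, seed=seeds["indicators"])

    files = {
        "bacteria_counts": "bacteria_counts.tsv",
        "fungi_counts": "fungi_counts.tsv",
        "bacteria_taxonomy": "bacteria_taxonomy.tsv",
        "fungi_taxonomy": "fungi_taxonomy.tsv",
        "metadata": "metadata.tsv",
        "indicators": "indicators.tsv",
        "indicator_directions": "indicator_directions.tsv",
    }
    write_feature_table(bt, outdir / files["bacteria_counts"])
    write_feature_table(ft, outdir / files["fungi_counts"])
    write_taxonomy(generate_taxonomy(bacteria, seed=seeds["bacteria"]), outdir / files["bacteria_taxonomy"])
    write_taxonomy(generate_taxonomy(fungi, seed=seeds["fungi"]), outdir / files["fungi_taxonomy"])
    write_metadata(meta, outdir / files["metadata"])
    write_indicator_table(ind, outdir / files["indicators"], outdir / files["indicator_directions"])

    manifest = {
        "seed": design.seed,
        "stage_seeds": seeds,
        "design": asdict(design) | {"treatments": list(design.treatments)},
        "bacteria_model": asdict(bacteria),
        "fungi_model": asdict(fungi),
        "indicator_model": {
            "params": indicators.params,
            "directions": indicators.directions,
            "units": indicators.units,
        },
        "files": files,
        "checksums": {
            name: hashlib.sha256((outdir / fn).read_bytes()).hexdigest()
            for name, fn in files.items()
        },
    }
    with (outdir / "manifest.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
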