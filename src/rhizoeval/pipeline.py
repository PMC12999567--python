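"""Pipeline orchestration: simulate → diversity → network → conformity →
associate, with a YAML config, per-stage seeds derived from one global
seed, a run manifest, and a consolidated report."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    factor_distance,
    mantel_test,
    significance_stars,
    spearman_factor_matrix,
)
from .conformity import anova_tukey_cld, evaluate_conformity
from .diversity import bray_curtis, pcoa, permanova, rarefy, simpson_index
from .io import (
    FeatureTable,
    read_feature_table,
    read_indicator_table,
    read_metadata,
    write_distance_matrix,
    write_network,
)
from .network import (
    NetworkParams,
    build_network,
    correlation_matrix,
    prevalence_filter,
    robustness,
    topology,
    TopologySummary,
)
from .simulate import (
    CommunityModel,
    StudyDesign,
    default_bacterial_model,
    default_fungal_model,
    default_indicator_model,
    generate_study,
    stage_seed,
)

log = logging.getLogger("rhizoeval")

STAGES = ("simulate", "diversity", "network", "conformity", "associate")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "rhizoeval_run",
    "inputs": {
        # set these to skip simulation and analyse your own study bundle
        "bacteria_counts": None,
        "fungi_counts": None,
        "metadata": None,
        "indicators": None,
        "indicator_directions": None,
    },
    "simulate": {
        "replicates": 5,
        "depth_median": 20000,
        "depth_sigma": 0.25,
        "bacteria": {},   # CommunityModel field overrides
        "fungi": {},
        "include_leaf_indicators": True,
    },
    "diversity": {
        "n_perm": 999,
    },
    "network": {
        "prevalence": 0.5,
        "r_threshold": 0.8,
        "alpha": 0.05,
        "method": "pearson",
        "robustness_reps": 50,
    },
    "conformity": {
        "control": "Ctrl",
        "weight_method": "pearson",
    },
    "associate": {
        "n_perm": 999,
        "soil_prefix_exclude": ("leaf_", "low_grade"),  # split soil vs leaf factors
    },
}


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and key not in ("bacteria", "fungi"):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_strict(defaults[key], val, path=f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file; unknown keys error."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge_strict(cfg, user)
    if overrides:
        cfg = _merge_strict(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: dict, outdir: Path) -> dict:
    """Either load user-supplied tables or simulate the default study."""
    paths = cfg["inputs"]
    user = {k: v for k, v in paths.items() if v}
    if user:
        required = ("bacteria_counts", "fungi_counts", "metadata", "indicators")
        for key in required:
            if not paths.get(key):
                raise ValueError(f"input {key!r} is required when supplying inputs")
            if not Path(paths[key]).exists():
                raise FileNotFoundError(f"input file not found: {paths[key]}")
        bundle_dir = None
    else:
        sim = cfg["simulate"]
        design = StudyDesign(
            replicates=sim["replicates"],
            depth_median=sim["depth_median"],
            depth_sigma=sim["depth_sigma"],
            seed=stage_seed(cfg["seed"], 0),
        )
        bact = dataclasses.replace(default_bacterial_model(), **sim["bacteria"])
        fung = dataclasses.replace(default_fungal_model(), **sim["fungi"])
        bundle_dir = outdir / "simulate"
        generate_study(
            design,
            bacteria=bact,
            fungi=fung,
            indicators=default_indicator_model(sim["include_leaf_indicators"]),
            outdir=bundle_dir,
            force=True,
        )
        paths = {
            "bacteria_counts": bundle_dir / "bacteria_counts.tsv",
            "fungi_counts": bundle_dir / "fungi_counts.tsv",
            "metadata": bundle_dir / "metadata.tsv",
            "indicators": bundle_dir / "indicators.tsv",
            "indicator_directions": bundle_dir / "indicator_directions.tsv",
        }
    tables = {
        "bacteria": read_feature_table(paths["bacteria_counts"]),
        "fungi": read_feature_table(paths["fungi_counts"]),
        "metadata": read_metadata(paths["metadata"]),
        "indicators": read_indicator_table(
            paths["indicators"], paths.get("indicator_directions")
        ),
    }
    return {"tables": tables, "paths": {k: str(v) for k, v in paths.items() if v},
            "simulated": bundle_dir is not None}


def _run_diversity(tables: dict, cfg: dict, outdir: Path, seed: int) -> list[Path]:
    files = []
    meta = tables["metadata"]
    alpha_rows = []
    for k, kingdom in enumerate(("bacteria", "fungi")):
        rt = rarefy(tables[kingdom], seed=stage_seed(seed, k))
        tables[f"{kingdom}_rarefied"] = rt
        dm = bray_curtis(rt)
        tables[f"{kingdom}_bray"] = dm
        write_distance_matrix(dm, outdir / f"{kingdom}_braycurtis.tsv")
        files.append(outdir / f"{kingdom}_braycurtis.tsv")
        simp = simpson_index(rt)
        for sid, v in simp.items():
            alpha_rows.append({"kingdom": kingdom, "sample_id": sid,
                               "treatment": meta.frame.loc[sid, "treatment"],
                               "simpson_dominance": v,
                               "simpson_complement": 1 - v})
        ord_res = pcoa(dm)
        coords = ord_res.coordinates.iloc[:, :2].copy()
        coords.index.name = "sample_id"
        coords.loc["explained_pct"] = ord_res.proportion_explained[:2]
        coords.to_csv(outdir / f"{kingdom}_pcoa.tsv", sep="\t")
        files.append(outdir / f"{kingdom}_pcoa.tsv")
        perm = permanova(dm, meta.grouping(list(dm.ids)),
                         n_perm=cfg["diversity"]["n_perm"],
                         seed=stage_seed(seed, 10 + k))
        pd.DataFrame([{
            "kingdom": kingdom, "pseudo_F": perm.f, "p": perm.p,
            "n_perm": perm.n_perm, "n_ge": perm.n_ge,
            "n_groups": perm.n_groups, "n_samples": perm.n_samples,
        }]).to_csv(outdir / f"{kingdom}_permanova.tsv", sep="\t", index=False)
        files.append(outdir / f"{kingdom}_permanova.tsv")
    pd.DataFrame(alpha_rows).to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False)
    files.append(outdir / "alpha_diversity.tsv")
    return files


def _run_network(tables: dict, cfg: dict, outdir: Path, seed: int) -> list[Path]:
    ncfg = cfg["network"]
    params = NetworkParams(
        prevalence=ncfg["prevalence"], r_threshold=ncfg["r_threshold"],
        alpha=ncfg["alpha"], method=ncfg["method"],
    )
    meta = tables["metadata"]
    files, topo_rows, robust_rows = [], [], []
    for kingdom in ("bacteria", "fungi"):
        table = tables[f"{kingdom}_rarefied"]
        # prevalence filtering on ALL samples before per-treatment correlation
        filtered = prevalence_filter(table, params.prevalence)
        for t in meta.treatments:
            sids = [s for s in filtered.sample_ids
                    if meta.frame.loc[s, "treatment"] == t]
            sub = FeatureTable(filtered.counts[sids].copy())
            r, p = correlation_matrix(sub, method=params.method)
            g = build_network(r, p, params)
            stem = f"{kingdom}_{t}"
            write_network(g, outdir / f"{stem}_edges.tsv", "edgelist_tsv")
            write_network(g, outdir / f"{stem}.graphml", "graphml")
            files += [outdir / f"{stem}_edges.tsv", outdir / f"{stem}.graphml"]
            topo = topology(g, seed=stage_seed(seed, 5))
            topo_rows.append({"kingdom": kingdom, "treatment": t, **topo.as_row()})
            if g.number_of_nodes() >= 2:
                rob = robustness(g, n_rep=ncfg["robustness_reps"],
                                 seed=stage_seed(seed, 6))
                for f_, m_ in zip(rob.fractions, rob.mean_giant_fraction):
                    robust_rows.append({"kingdom": kingdom, "treatment": t,
                                        "removed_fraction": round(float(f_), 4),
                                        "mean_giant_fraction": m_, "auc": rob.auc})
    cols = ["kingdom", "treatment", *TopologySummary.COLUMNS]
    pd.DataFrame(topo_rows)[cols].to_csv(outdir / "topology.tsv", sep="\t", index=False)
    pd.DataFrame(robust_rows).to_csv(outdir / "robustness.tsv", sep="\t", index=False)
    files += [outdir / "topology.tsv", outdir / "robustness.tsv"]
    return files


def _run_conformity(tables: dict, cfg: dict, outdir: Path) -> list[Path]:
    tbl = tables["indicators"]
    res = evaluate_conformity(tbl, control=cfg["conformity"]["control"],
                              weight_method=cfg["conformity"]["weight_method"])
    res.weights.rename("weight").to_frame().rename_axis("indicator").to_csv(
        outdir / "weights.tsv", sep="\t")
    res.membership.rename_axis("treatment").to_csv(outdir / "membership.tsv", sep="\t")
    scores = pd.DataFrame({
        "score": res.scores.round(3),
        "improvement_pct": res.improvement_pct,
    }).rename_axis("treatment")
    scores.to_csv(outdir / "conformity_scores.tsv", sep="\t")
    rows = []
    for ind in tbl.indicators:
        gc = anova_tukey_cld(tbl, ind)
        for t in gc.means.index:
            rows.append({
                "indicator": ind, "treatment": t,
                "mean": gc.means[t], "sd": gc.sds[t], "n": gc.n[t],
                "letters": gc.letters[t], "anova_F": gc.f, "anova_p": gc.p,
                "degenerate": gc.degenerate,
            })
    pd.DataFrame(rows).to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
    return [outdir / f for f in
            ("weights.tsv", "membership.tsv", "conformity_scores.tsv", "group_comparison.tsv")]


def _run_associate(tables: dict, cfg: dict, outdir: Path, seed: int) -> list[Path]:
    acfg = cfg["associate"]
    frame = tables["indicators"].sample_frame()
    prefixes = tuple(acfg["soil_prefix_exclude"])
    soil = [c for c in frame.columns if not c.startswith(prefixes)]
    leaf = [c for c in frame.columns if c.startswith(prefixes)]
    factor_sets = {"soil": soil}
    if leaf:
        factor_sets["leaf"] = leaf
    rows = []
    for kingdom in ("bacteria", "fungi"):
        dm = tables[f"{kingdom}_bray"]
        sub = frame.loc[list(dm.ids)]
        for name, facs in factor_sets.items():
            fd = factor_distance(sub, facs)
            res = mantel_test(dm, fd, n_perm=acfg["n_perm"],
                              seed=stage_seed(seed, 7))
            rows.append({"kingdom": kingdom, "factor_set": name,
                         "mantel_r": res.r, "p": res.p,
                         "stars": significance_stars(res.p),
                         "n_perm": res.n_perm})
    pd.DataFrame(rows).to_csv(outdir / "mantel.tsv", sep="\t", index=False)
    rho, pval = spearman_factor_matrix(frame)
    rho.rename_axis("factor").to_csv(outdir / "factor_spearman_rho.tsv", sep="\t")
    pval.rename_axis("factor").to_csv(outdir / "factor_spearman_p.tsv", sep="\t")
    # BH-adjusted companion column for users (the Mantel/Spearman panel
    # itself is reported unadjusted)
    iu = np.triu_indices(len(rho), k=1)
    flat = pval.to_numpy()[iu]
    finite = np.isfinite(flat)
    adj = np.full(flat.shape, np.nan)
    if finite.any():
        from scipy.stats import false_discovery_control

        adj[finite] = false_discovery_control(flat[finite])
    pd.DataFrame({
        "factor_a": [rho.index[i] for i in iu[0]],
        "factor_b": [rho.columns[j] for j in iu[1]],
        "rho": rho.to_numpy()[iu], "p": flat, "p_bh": adj,
        "stars": [significance_stars(v) for v in flat],
    }).to_csv(outdir / "factor_spearman_pairs.tsv", sep="\t", index=False)
    return [outdir / f for f in
            ("mantel.tsv", "factor_spearman_rho.tsv", "factor_spearman_p.tsv",
             "factor_spearman_pairs.tsv")]


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run all stages and write ``manifest.yaml`` last; returns the manifest.

    Any stage failure aborts with the stage name in the exception and a
    ``<stage>.partial`` marker left in the output directory.
    """
    cfg = _merge_strict(DEFAULT_CONFIG, config) if config is not DEFAULT_CONFIG else config
    outdir = Path(outdir if outdir is not None else cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    stage_seeds = {s: stage_seed(seed, i) for i, s in enumerate(STAGES)}
    outputs: dict[str, list[str]] = {}

    def run_stage(name: str, fn):
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        marker = stage_dir / f"{name}.partial"
        marker.write_text("in progress\n")
        log.info("stage %s starting", name)
        try:
            produced = fn(stage_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        marker.unlink()
        outputs[name] = [str(p.relative_to(outdir)) for p in produced]
        log.info("stage %s done (%d files)", name, len(produced))

    loaded = _load_inputs(cfg, outdir)
    tables = loaded["tables"]
    if loaded["simulated"]:
        outputs["simulate"] = sorted(
            str(p.relative_to(outdir)) for p in (outdir / "simulate").iterdir()
        )
    run_stage("diversity", lambda d: _run_diversity(tables, cfg, d, stage_seeds["diversity"]))
    run_stage("network", lambda d: _run_network(tables, cfg, d, stage_seeds["network"]))
    run_stage("conformity", lambda d: _run_conformity(tables, cfg, d))
    run_stage("associate", lambda d: _run_associate(tables, cfg, d, stage_seeds["associate"]))

    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config": _yaml_safe(cfg),
        "inputs": loaded["paths"],
        "outputs": outputs,
        "checksums": {
            f: _sha256(outdir / f) for files in outputs.values() for f in files
        },
    }
    with (outdir / "manifest.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def report(outdir) -> str:
    """Consolidated human-readable summary of a completed run.

    Regenerating from the same manifest is idempotent.  Raises if stages
    are missing.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.yaml"
    if not manifest_path.exists():
        raise ValueError(f"no manifest.yaml under {outdir}; run the pipeline first")
    with manifest_path.open("r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    missing = [s for s in ("diversity", "network", "conformity", "associate")
               if s not in manifest.get("outputs", {})]
    if missing:
        raise ValueError(f"incomplete run; missing stages: {missing}")

    lines = [
        "# rhizoeval run report",
        f"seed: {manifest['seed']}  version: {manifest['version']}",
        "",
        "## Indicator comparison (mean ± SD, Tukey letters)",
    ]
    gc = pd.read_csv(outdir / "conformity" / "group_comparison.tsv", sep="\t")
    for ind, sub in gc.groupby("indicator", sort=False):
        cells = [
            f"{row.mean:.2f} ± {row.sd:.2f} {row.letters} ({row.treatment})"
            for row in sub.itertuples(index=False)
        ]
        lines.append(f"- {ind}: " + "; ".join(cells))
    lines += ["", "## Conformity scores"]
    scores = pd.read_csv(outdir / "conformity" / "conformity_scores.tsv", sep="\t")
    for row in scores.itertuples(index=False):
        lines.append(
            f"- {row.treatment}: score {row.score:.3f}"
            f" ({row.improvement_pct:+.1f}% vs control)"
        )
    lines += ["", "## Network topology"]
    topo = pd.read_csv(outdir / "network" / "topology.tsv", sep="\t")
    lines.append("\t".join(topo.columns))
    for row in topo.itertuples(index=False):
        lines.append("\t".join(str(v) for v in row))
    lines += ["", "## Mantel panel"]
    mantel = pd.read_csv(outdir / "associate" / "mantel.tsv", sep="\t",
                         keep_default_na=False)
    for row in mantel.itertuples(index=False):
        lines.append(
            f"- {row.kingdom} ~ {row.factor_set}: r = {row.mantel_r:.3f},"
            f" p = {row.p:.3f} {row.stars}"
        )
    lines += ["", "## PERMANOVA"]
    for kingdom in ("bacteria", "fungi"):
        pv = pd.read_csv(outdir / "diversity" / f"{kingdom}_permanova.tsv", sep="\t")
        r = pv.iloc[0]
        lines.append(
            f"- {kingdom}: pseudo-F = {r['pseudo_F']:.3f}, p = {r['p']:.3f}"
            f" ({int(r['n_perm'])} permutations)"
        )
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text, encoding="utf-8")
    return text
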