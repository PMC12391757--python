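"""End-to-end orchestration: data -> features -> disconnection -> models
-> voxel-wise inference -> reports.

One :class:`RunConfig` drives the whole run.  A single global seed is
fanned out to per-stage sub-seeds by fixed offsets, so any stage can be
re-run in isolation yet the full run stays reproducible; every product
is written under the output directory and listed in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_features import (
    DEFAULT_EXCLUSION_PCT,
    build_design_matrix,
    compute_overlap,
    apply_exclusion,
    write_design_matrix,
)
from .functional_disconnection import (
    DEFAULT_R_MIN,
    functional_disconnection_map,
    threshold_map,
)
from .outcome_prediction import (
    benchmark_model,
    combined_model,
    compare_models,
    fit_lasso_loo,
    lambda_grid,
)
from .structural_disconnection import (
    DEFAULT_HIT_MIN,
    DEFAULT_P_MIN,
    structural_disconnectivity_map,
    threshold_structural,
    tract_overlap_report,
)
from .synthetic_data import (
    SyntheticConfig,
    SyntheticDataset,
    generate_dataset,
    load_cohort,
    write_cohort,
)
from .volume_io import save_volume
from .voxelwise_inference import (
    TfceParams,
    network_outcome_correlation,
    permutation_fwe,
)

log = logging.getLogger("netlesion")

# fixed offsets for per-stage sub-seeds
_SEED_OFFSET_DATA = 0
_SEED_OFFSET_PERM = 104729


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # synthetic | directory
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    data_dir: str | None = None
    outdir: str = "netlesion_out"
    seed: int = 0
    r_min: float = DEFAULT_R_MIN
    p_min: float = DEFAULT_P_MIN
    hit_min: float = DEFAULT_HIT_MIN
    exclusion_pct: float = DEFAULT_EXCLUSION_PCT
    grid_n: int = 100
    grid_low: float = 1e-5
    grid_high: float = 1e5
    n_perm: int = 500
    alpha: float = 0.01
    tfce: TfceParams = field(default_factory=TfceParams)
    write_cohort_dir: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ValueError("mode must be 'synthetic' or 'directory'")
        if self.mode == "directory" and not self.data_dir:
            raise ValueError("directory mode requires data_dir")
        if not -1 <= self.r_min <= 1 or not 0 <= self.p_min <= 1:
            raise ValueError("thresholds out of range")
        if self.exclusion_pct < 0:
            raise ValueError("exclusion_pct must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        tf = raw.pop("tfce", None)
        cfg = cls(**raw)
        if syn:
            if "grid_shape" in syn:
                syn["grid_shape"] = tuple(syn["grid_shape"])
            if "outcome_weights" in syn and syn["outcome_weights"] is not None:
                syn["outcome_weights"] = {
                    int(k): float(v) for k, v in syn["outcome_weights"].items()
                }
            cfg.synthetic = SyntheticConfig(**syn)
        if tf:
            cfg.tfce = TfceParams(**tf)
        return cfg


def _load_or_generate(config: RunConfig) -> SyntheticDataset:
    if config.mode == "directory":
        return load_cohort(config.data_dir, config.synthetic)
    syn = dataclasses.replace(config.synthetic, seed=config.seed + _SEED_OFFSET_DATA)
    return generate_dataset(syn)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_echo(config),
        "versions": {"netlesion": __version__, "numpy": np.__version__},
        "products": {},
        "metrics": {},
        "stages": [],
    }

    def stage(name):
        t0 = time.time()

        def done():
            manifest["stages"].append({"name": name, "seconds": round(time.time() - t0, 3)})
            log.info("stage %s done in %.2fs", name, time.time() - t0)

        return done

    # ---- data ------------------------------------------------------------
    fin = stage("data")
    try:
        ds = _load_or_generate(config)
    except Exception as e:  # pragma: no cover - error path
        raise RuntimeError(f"stage 'data' failed: {e}") from e
    if config.mode == "synthetic" and config.write_cohort_dir:
        cohort_dir = write_cohort(ds, out / "cohort")
        manifest["products"]["cohort_dir"] = str(cohort_dir)
    fin()

    y = ds.cohort.outcomes["mrs"].to_numpy(dtype=float)
    records = ds.cohort.outcomes
    grid = lambda_grid(config.grid_n, config.grid_low, config.grid_high)

    # ---- atlas features --------------------------------------------------
    fin = stage("features")
    design = {}
    feature_tables = []
    for kind, atlas in ds.atlases.items():
        feats = []
        for lesion in ds.cohort.lesions:
            f = compute_overlap(lesion, atlas)
            apply_exclusion(f, config.exclusion_pct)
            feats.append(f)
        X = build_design_matrix(feats, atlas)
        path = write_design_matrix(X, out / f"features_{kind}.tsv")
        design[kind] = X
        feature_tables.append(str(path))
    manifest["products"]["feature_tables"] = feature_tables
    fin()

    # ---- disconnection maps ----------------------------------------------
    fin = stage("disconnect")
    fdisc, sdisc = [], []
    for lesion in ds.cohort.lesions:
        fm = functional_disconnection_map(lesion, ds.connectome)
        fdisc.append(threshold_map(fm, config.r_min))
        save_volume(
            out / "fdisc" / f"{lesion.subject_id}_fdisc.nii.gz", ds.grid, fm.values
        )
        sm = structural_disconnectivity_map(lesion, ds.tracts, hit_min=config.hit_min)
        sdisc.append(threshold_structural(sm, config.p_min))
        save_volume(
            out / "sdisc" / f"{lesion.subject_id}_sdisc.nii.gz", ds.grid, sm.values
        )
    manifest["products"]["fdisc_dir"] = str(out / "fdisc")
    manifest["products"]["sdisc_dir"] = str(out / "sdisc")
    fin()

    # ---- outcome prediction ----------------------------------------------
    fin = stage("predict")
    results = []
    for kind, X in design.items():
        res = fit_lasso_loo(X, records["mrs"], grid, model_id=kind)
        results.append(res)
        comb = combined_model(
            X, records, grid, atlas_result=res, model_id=f"{kind}+covariates"
        )
        results.append(comb)
    bench = benchmark_model(records, grid)
    results.append(bench)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for r in results:
        (models_dir / f"{r.model_id}.json").write_text(json.dumps(r.to_dict(), indent=1))
    comparison = compare_models(results)
    comparison.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
    manifest["products"]["model_comparison"] = str(out / "model_comparison.tsv")
    manifest["products"]["models"] = sorted(str(p) for p in models_dir.glob("*.json"))
    manifest["metrics"]["model_r2"] = {
        r.model_id: r.r2 for r in results
    }
    manifest["metrics"]["delta_vs_atlas_only"] = {
        r.model_id: r.delta_vs_benchmark
        for r in results
        if r.delta_vs_benchmark is not None
    }
    fin()

    # ---- voxel-wise inference --------------------------------------------
    fin = stage("voxelwise")
    feature_maps = {
        "lesion": np.stack([l.data.astype(float) for l in ds.cohort.lesions]),
        "functional": np.stack([m.values for m in fdisc]),
        "structural": np.stack([m.values for m in sdisc]),
    }
    inference_products = {}
    sig_counts = {}
    sdisc_sig_pos = None
    for feat, maps in feature_maps.items():
        for direction in ("positive", "negative"):
            res = permutation_fwe(
                maps,
                y,
                ds.brainmask,
                params=config.tfce,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=config.seed + _SEED_OFFSET_PERM,
                direction=direction,
            )
            tag = f"{feat}_{'pos' if direction == 'positive' else 'neg'}"
            bundle = {}
            for name, arr in (
                ("tstat", res.t_observed),
                ("tfce", res.tfce_observed),
                ("fwep", res.fwe_p),
                ("sig", res.significant),
            ):
                p = save_volume(out / "stats" / f"{tag}_{name}.nii.gz", ds.grid, arr)
                bundle[name] = str(p)
            inference_products[tag] = bundle
            sig_counts[tag] = int(res.significant.sum())
            if feat == "structural" and direction == "positive":
                sdisc_sig_pos = res.significant
    manifest["products"]["inference"] = inference_products
    manifest["metrics"]["n_significant_voxels"] = sig_counts
    fin()

    # ---- reports ----------------------------------------------------------
    fin = stage("reports")
    net_corr = network_outcome_correlation(fdisc, ds.atlases["functional"], y)
    net_corr.to_csv(out / "network_outcome_correlation.tsv", sep="\t", index=False)
    manifest["products"]["network_outcome_correlation"] = str(
        out / "network_outcome_correlation.tsv"
    )
    report = tract_overlap_report(
        sdisc_sig_pos if sdisc_sig_pos is not None else np.zeros(ds.grid.shape),
        ds.tracts,
    )
    report.to_csv(out / "tract_overlap_report.tsv", sep="\t", index=False)
    manifest["products"]["tract_overlap_report"] = str(out / "tract_overlap_report.tsv")
    manifest["metrics"]["network_r2"] = {
        row["name"]: row["r2"] for _, row in net_corr.iterrows()
    }
    fin()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(config)
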