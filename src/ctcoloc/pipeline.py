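"""Pipeline orchestration: config, seeds, caching, end-to-end runs.

A run is described by a single YAML config (synthetic scenario or paths to
user-supplied tables) and executed stage by stage in method order:
generate/load inputs -> factor reduction -> change windows -> surrogate
ensembles -> univariate/multivariate scans -> dominance -> influence maps
-> gene-expression validation -> subject-level cohort transfer.  Every
stage writes plain tabular outputs into the run directory, surrogate
ensembles are cached on disk keyed by map name, seed and parameters, and a
provenance manifest records seeds, parameters and library versions; reruns
with the same config and seeds are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_reduction import reduce_modality
from .cohort_subject_level import (cohort_average_change,
                                   group_mean_null_test, subject_change,
                                   subject_dominance)
from .colocalization_scan import (add_fdr, coloc_trajectory,
                                  multivariate_scan, univariate_scan)
from .ct_change_windows import (CTTrajectorySet, build_windows,
                                extract_change_series,
                                residualize_on_baseline)
from .dominance_influence import dominance_scan, influence_map
from .gene_trajectory_validation import trajectory_test
from .parcel_core import (AtlasSet, ParcelMap, read_parcel_table,
                          write_parcel_table)
from .spatial_nulls import NullEnsemble, generate_surrogates, \
    pairwise_distances
from .synthetic_data import (CohortData, ExpressionDataset, GroundTruth,
                             ParcelGeometry, make_atlas_library, make_cohort,
                             make_ct_trajectories, make_expression_dataset,
                             make_parcel_geometry)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("ctcoloc.pipeline")

ALL_STAGES = ("synth", "reduce", "windows", "nulls", "scan-univariate",
              "scan-multivariate", "dominance", "influence",
              "gene-validate", "subject-scan")

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "ctcoloc_run",
    "n_nulls": 10_000,
    "percentile": 50,
    "sex": "average",
    "baseline_correction": False,
    "windows": {"start": 5.0, "end": 90.0, "length": 5.0, "step": 1.0,
                "extras": [[5.0, 30.0]]},
    "reduce": {"enabled": False, "retention_threshold": 0.01,
               "prefix": "ni"},
    "stages": list(ALL_STAGES),
    "synthetic": None,
    "inputs": None,
}

_SYNTH_DEFAULTS: dict = {
    "n_per_hemisphere": 74,
    "n_predictors": 9,
    "length_scale": 25.0,
    "cross_correlation": 0.3,
    "mixture": {"atlas1": 0.5, "atlas2": 0.3},
    "construction_r2": 0.6,
    "target_window": [10.0, 15.0],
    "age_drift": 0.05,
    "expression": {"n_subjects": 33, "n_signal_genes": 50,
                   "n_flat_genes": 50, "n_nonbrain_pool": 2154,
                   "effect_size": 2.0, "genes_per_set": 5},
    "cohort": {"n_subjects": 100, "n_sites": 20, "subject_sd": 0.05,
               "site_sd": 0.02, "noise_sd": 0.02,
               "session_ages": [10.0, 12.0]},
}


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Fully resolved run configuration (defaults filled in)."""

    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def out_dir(self) -> Path:
        return Path(self.raw["out_dir"])

    def emit(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.raw, sort_keys=True))
        return path


def _merge_defaults(user: dict, defaults: dict, context: str) -> dict:
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s) in {context}: "
                          f"{sorted(unknown)}")
    out = {}
    for key, dflt in defaults.items():
        val = user.get(key, dflt)
        if isinstance(dflt, dict) and isinstance(val, dict) and val is not dflt:
            val = _merge_defaults(val, dflt, f"{context}.{key}")
        out[key] = val
    return out


def validate_config(path_or_dict: str | Path | dict) -> RunConfig:
    """Load, default-fill and validate a run config."""
    if isinstance(path_or_dict, (str, Path)):
        p = Path(path_or_dict)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        user = yaml.safe_load(p.read_text()) or {}
    else:
        user = dict(path_or_dict)
    cfg = _merge_defaults(user, _DEFAULTS, "config")
    if cfg["synthetic"] is None and cfg["inputs"] is None:
        cfg["synthetic"] = {}
    if cfg["synthetic"] is not None:
        cfg["synthetic"] = _merge_defaults(cfg["synthetic"], _SYNTH_DEFAULTS,
                                           "config.synthetic")
    if cfg["inputs"] is not None:
        for key, val in cfg["inputs"].items():
            if val is not None and not Path(val).exists():
                raise ConfigError(f"inputs.{key}: file not found: {val}")
    w = cfg["windows"]
    if w["end"] < w["start"] + w["length"]:
        raise ConfigError(
            f"window length {w['length']} does not fit the range "
            f"[{w['start']}, {w['end']}]")
    if w["length"] <= 0 or w["step"] <= 0:
        raise ConfigError("window length and step must be positive")
    bad = [s for s in cfg["stages"] if s not in ALL_STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s) {bad}; valid: {ALL_STAGES}")
    if cfg["n_nulls"] < 1:
        raise ConfigError("n_nulls must be >= 1")
    return RunConfig(cfg)


def _geometry_to_tsv(geom: ParcelGeometry, path: Path) -> None:
    pd.DataFrame({"parcel": geom.parcel_ids,
                  "hemisphere": geom.hemisphere,
                  "x": geom.centroid_coords[:, 0],
                  "y": geom.centroid_coords[:, 1],
                  "z": geom.centroid_coords[:, 2]}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def _geometry_from_tsv(path: Path) -> ParcelGeometry:
    df = pd.read_csv(path, sep="\t")
    return ParcelGeometry(tuple(df["parcel"].astype(str)),
                          df[["x", "y", "z"]].to_numpy(float),
                          tuple(df["hemisphere"].astype(str)))


def _null_cache_key(name: str, n: int, seed: int, params: dict) -> str:
    blob = json.dumps([name, n, seed, params], sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


def cached_surrogates(pmap: ParcelMap, dist, n: int, seed: int,
                      cache_dir: Path) -> NullEnsemble:
    """Generate (or load from cache) one map's surrogate ensemble."""
    ens_params = {"n_bins": 25, "knn_fracs": (0.05, 0.5), "n_scales": 8,
                  "resample": True}
    key = _null_cache_key(pmap.name, n, seed,
                          {**ens_params,
                           "knn_fracs": list(ens_params["knn_fracs"])})
    cache_dir.mkdir(parents=True, exist_ok=True)
    f = cache_dir / f"nulls_{pmap.name}_{key}.npz"
    if f.exists():
        dat = np.load(f, allow_pickle=False)
        logger.info("nulls: cache hit for %s (%s)", pmap.name, f.name)
        return NullEnsemble(pmap.name, tuple(pmap.parcel_ids),
                            dat["surrogates"], seed, ens_params)
    ens = generate_surrogates(pmap, dist, n, seed, **ens_params)
    np.savez_compressed(f, surrogates=ens.surrogates)
    return ens


class PipelineState:
    """File-backed shared state between stages of one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = config.out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.geometry: ParcelGeometry | None = None
        self.atlases: AtlasSet | None = None
        self.predictors: AtlasSet | None = None
        self.trajectories: CTTrajectorySet | None = None
        self.truth: GroundTruth | None = None
        self.expression: ExpressionDataset | None = None
        self.cohort: CohortData | None = None
        self.changes = None
        self.windows = None
        self.nulls: dict[str, NullEnsemble] = {}

    # -- loading helpers so stages can run piecemeal across processes --
    def need_geometry(self) -> ParcelGeometry:
        if self.geometry is None:
            f = self.out / "geometry.tsv"
            inputs = self.config["inputs"] or {}
            src = Path(inputs.get("geometry_table") or f)
            if not src.exists():
                raise FileNotFoundError(
                    f"geometry not available ({src}); run the synth stage "
                    f"or provide inputs.geometry_table")
            self.geometry = _geometry_from_tsv(src)
        return self.geometry

    def need_predictors(self) -> AtlasSet:
        if self.predictors is None:
            f = self.out / "predictors.tsv"
            if not f.exists():
                raise FileNotFoundError(
                    "predictors.tsv missing; run synth/reduce first")
            self.predictors = read_parcel_table(f).zscored()
        return self.predictors

    def need_trajectories(self) -> CTTrajectorySet:
        if self.trajectories is None:
            inputs = self.config["inputs"] or {}
            f = Path(inputs.get("trajectory_table")
                     or self.out / "trajectories.tsv")
            if not f.exists():
                raise FileNotFoundError(f"trajectory table missing ({f})")
            self.trajectories = CTTrajectorySet.read_tsv(f)
        return self.trajectories

    def need_changes(self):
        if self.changes is None:
            raise RuntimeError("windows stage must run before scans")
        return self.changes


def _stage_synth(state: PipelineState) -> None:
    cfg = state.config
    syn = cfg["synthetic"]
    if syn is None:
        inputs = cfg["inputs"] or {}
        state.geometry = state.need_geometry()
        if inputs.get("atlas_table"):
            state.atlases = read_parcel_table(inputs["atlas_table"]).zscored()
        if inputs.get("cohort_table"):
            state.cohort = CohortData.read_tsv(inputs["cohort_table"])
        if inputs.get("expression_matrix"):
            mat = pd.read_csv(inputs["expression_matrix"], index_col=0)
            subj = pd.read_csv(inputs["expression_subjects"], sep="\t")
            state.expression = ExpressionDataset(
                tuple(subj["subject"].astype(str)),
                subj["age"].to_numpy(float), tuple(mat.index),
                mat.to_numpy(float).T, {}, list(mat.index))
        state.trajectories = state.need_trajectories()
        return
    seed = int(cfg["seed"])
    geom = make_parcel_geometry(syn["n_per_hemisphere"], seed)
    atlases = make_atlas_library(
        geom, syn["n_predictors"], syn["length_scale"],
        syn["cross_correlation"], seed + 1)
    weights = np.zeros(len(atlases))
    for name, w in syn["mixture"].items():
        weights[atlases.names.index(name)] = w
    truth = GroundTruth(weights, construction_r2=syn["construction_r2"],
                        seed=seed + 2)
    traj, realized = make_ct_trajectories(
        geom, atlases, truth, target_window=tuple(syn["target_window"]),
        age_drift=syn["age_drift"])
    expr = make_expression_dataset(seed=seed + 3, **syn["expression"])
    cohort = make_cohort(geom, traj, seed=seed + 4,
                         session_ages=tuple(
                             syn["cohort"].pop("session_ages")),
                         **{k: v for k, v in syn["cohort"].items()})
    syn["cohort"]["session_ages"] = list(cohort.ages[0])

    _geometry_to_tsv(geom, state.out / "geometry.tsv")
    write_parcel_table(atlases, state.out / "atlases.tsv")
    write_parcel_table(atlases, state.out / "predictors.tsv")
    traj.write_tsv(state.out / "trajectories.tsv")
    cohort.write_tsv(state.out / "cohort.tsv")
    expr.write(state.out / "expression.csv", state.out / "subjects.tsv")
    (state.out / "ground_truth.json").write_text(json.dumps({
        "mixture_weights": dict(zip(atlases.names, weights.tolist())),
        "noise_sd": realized.noise_sd,
        "construction_r2": realized.construction_r2,
        "target_window": list(syn["target_window"]), "seed": seed},
        indent=2))
    state.geometry, state.atlases, state.trajectories = geom, atlases, traj
    state.predictors, state.expression, state.cohort = atlases, expr, cohort
    state.truth = realized


def _stage_reduce(state: PipelineState) -> None:
    cfg = state.config["reduce"]
    if not cfg["enabled"]:
        logger.info("reduce: disabled; predictors are the raw atlases")
        return
    atlases = state.atlases or read_parcel_table(
        state.out / "atlases.tsv").zscored()
    scores, sol = reduce_modality(atlases, cfg["retention_threshold"],
                                  cfg["prefix"])
    write_parcel_table(scores, state.out / "predictors.tsv")
    if sol is not None:
        sol.loadings.to_csv(state.out / "factor_loadings.tsv", sep="\t")
        sol.factor_correlations.to_csv(
            state.out / "factor_correlations.tsv", sep="\t")
        pd.DataFrame({
            "factor": sol.names,
            "unrotated_proportion": sol.variance_explained_unrotated,
            "rotated_proportion": sol.variance_explained_rotated,
            "rotated_cumulative":
                np.cumsum(sol.variance_explained_rotated)}).to_csv(
            state.out / "factor_variance.tsv", sep="\t", index=False)
    state.predictors = scores


def _stage_windows(state: PipelineState) -> None:
    cfg = state.config
    w = cfg["windows"]
    traj = state.need_trajectories()
    windows = build_windows(w["start"], w["end"], w["length"], w["step"],
                            [tuple(x) for x in w["extras"]])
    changes = extract_change_series(traj, windows, cfg["percentile"],
                                    cfg["sex"])
    if cfg["baseline_correction"]:
        changes = [residualize_on_baseline(
            ch, traj.slice_map(ch.window[0], cfg["percentile"], cfg["sex"]))
            for ch in changes]
    state.windows, state.changes = windows, changes
    df = pd.DataFrame({"parcel": list(traj.parcel_ids)})
    for ch in changes:
        df[f"dCT_{ch.window[0]:g}_{ch.window[1]:g}"] = ch.values
    df.to_csv(state.out / "change_maps.tsv", sep="\t", index=False,
              float_format="%.17g")


def _stage_nulls(state: PipelineState) -> None:
    cfg = state.config
    preds = state.need_predictors()
    dist = pairwise_distances(state.need_geometry())
    for i, m in enumerate(preds.maps):
        state.nulls[m.name] = cached_surrogates(
            m, dist, int(cfg["n_nulls"]), int(cfg["seed"]) + 1000 + i,
            state.out / "cache")


def _require_nulls(state: PipelineState) -> dict[str, NullEnsemble]:
    if not state.nulls:
        _stage_nulls(state)
    return state.nulls


def _stage_scan_univariate(state: PipelineState) -> None:
    preds = state.need_predictors()
    changes = state.need_changes()
    nulls = _require_nulls(state)
    frames = [univariate_scan(m, changes, nulls[m.name])
              for m in preds.maps]
    modality = [preds.modality.get(m.name, "all") for m in preds.maps]
    df = add_fdr(frames, modality)  # FDR within each modality
    df.to_csv(state.out / "scan_univariate.tsv", sep="\t", index=False)


def _stage_scan_multivariate(state: PipelineState) -> None:
    preds = state.need_predictors()
    changes = state.need_changes()
    nulls = _require_nulls(state)
    groups: dict[str, list[str]] = {}
    for m in preds.maps:
        groups.setdefault(preds.modality.get(m.name, "all"), []).append(
            m.name)
    frames = []
    for label, names in groups.items():
        if len(names) < 1:
            continue
        frames.append(multivariate_scan(preds.subset(names), changes,
                                        nulls, label=label))
    # corrected across all models and modalities: one family
    df = add_fdr(frames, ["combined"] * len(frames))
    df.to_csv(state.out / "scan_multivariate.tsv", sep="\t", index=False)


def _stage_dominance(state: PipelineState) -> None:
    preds = state.need_predictors()
    changes = state.need_changes()
    nulls = _require_nulls(state)
    results = dominance_scan(preds, changes, nulls,
                             n_null_iters=int(state.config["n_nulls"]))
    df = pd.concat([r.to_frame() for r in results], ignore_index=True)
    df.to_csv(state.out / "dominance.tsv", sep="\t", index=False)
    state._dominance_results = results


def _stage_influence(state: PipelineState) -> None:
    preds = state.need_predictors()
    changes = state.need_changes()
    # broad developmental window if present, else the last window
    target_change = changes[-1]
    maps = [influence_map(preds, target_change, nm) for nm in preds.names]
    df = pd.DataFrame({"parcel": list(preds.parcel_ids)})
    for m in maps:
        df[m.name] = m.values
    df.to_csv(state.out / "influence_maps.tsv", sep="\t", index=False,
              float_format="%.17g")


def _stage_gene_validate(state: PipelineState) -> None:
    expr = state.expression
    if expr is None:
        logger.info("gene-validate: no expression data; skipped")
        return
    period = expr.peak_period or tuple(
        state.config["synthetic"]["target_window"])
    markers = {name: (genes, period)
               for name, genes in expr.gene_sets.items()}
    res = trajectory_test(expr, markers,
                          n_null=int(state.config["n_nulls"]),
                          seed=int(state.config["seed"]) + 5000)
    res.to_csv(state.out / "gene_validation.tsv", sep="\t", index=False)


def _stage_subject_scan(state: PipelineState) -> None:
    cohort = state.cohort
    if cohort is None:
        f = state.out / "cohort.tsv"
        if not f.exists():
            logger.info("subject-scan: no cohort data; skipped")
            return
        cohort = CohortData.read_tsv(f)
    preds = state.need_predictors()
    nulls = _require_nulls(state)
    span = (cohort.session_labels[0], cohort.session_labels[-1])
    changes = subject_change(cohort, span)
    res = subject_dominance(changes, preds)
    res.to_csv(state.out / "subject_results.tsv", sep="\t", index=False)
    group = group_mean_null_test(
        changes, preds, nulls,
        n_null=min(int(state.config["n_nulls"]), 1000))
    (state.out / "group_test.json").write_text(json.dumps({
        "mean_full_model_r2": group["mean_full_model_r2"],
        "p_full": group["p_full"],
        "mean_dominance": group["mean_dominance"].to_dict(),
        "p_dominance": group["p_dominance"].to_dict(),
        "n_null": group["n_null"], "n_subjects": group["n_subjects"]},
        indent=2))


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "reduce": _stage_reduce,
    "windows": _stage_windows,
    "nulls": _stage_nulls,
    "scan-univariate": _stage_scan_univariate,
    "scan-multivariate": _stage_scan_multivariate,
    "dominance": _stage_dominance,
    "influence": _stage_influence,
    "gene-validate": _stage_gene_validate,
    "subject-scan": _stage_subject_scan,
}


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages in order; returns the output directory.

    A stage failure halts the run with a stage-scoped error; outputs of
    completed stages are retained.  A provenance manifest (seeds,
    parameters, versions) is written at the end.
    """
    state = PipelineState(config)
    config.emit(state.out / "config_resolved.yaml")
    t0 = time.time()
    for stage in config["stages"]:
        ts = time.time()
        logger.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](state)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", stage, time.time() - ts)
    manifest = {
        "ctcoloc_version": __version__,
        "seed": config["seed"],
        "n_nulls": config["n_nulls"],
        "stages": list(config["stages"]),
        "config": config.raw,
        "versions": {m.__name__: m.__version__
                     for m in (np, pd, yaml)},
        "elapsed_s": round(time.time() - t0, 2),
    }
    (state.out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return state.out
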