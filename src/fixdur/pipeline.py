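"""Pipeline orchestration: staged, resumable runs with a manifest.

Stages: features -> patches -> triplets -> fit -> report.  Every stage
writes its artifacts under the configured output directory; a manifest
records the config digest, seed and per-stage status so that a rerun with
an unchanged config skips completed stages and a changed config recomputes
them.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .feature_maps import compute_feature_maps
from .io import (
    PipelineConfig,
    load_feature_maps,
    read_fixation_table,
    read_scene_image,
    save_feature_maps,
    write_table,
)
from .lmm import (
    FULL_FIXED_TERMS,
    ModelSpec,
    build_design,
    fit_zcplmm,
    fixed_effect_tests,
    r2_lmm,
)
from .patch_stats import apply_edge_logit, patch_feature_table, px_radius_for_degrees
from .reporting import binned_summary
from .triplets import FEATURE_COLS, build_control_table, build_triplets

__all__ = ["run_pipeline", "simulate_study", "PipelineError"]

STAGES = ("features", "patches", "triplets", "fit", "report")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _model_spec(config: PipelineConfig) -> ModelSpec:
    model = config.model or {}
    fixed = tuple(model.get("fixed_terms", FULL_FIXED_TERMS))
    random = {
        factor: tuple(terms)
        for factor, terms in model.get(
            "random", {"subject_id": ["1"], "scene_id": ["1"]}
        ).items()
    }
    return ModelSpec(fixed_terms=fixed, random=random)


def _load_manifest(out: Path) -> dict:
    mpath = out / "manifest.json"
    if mpath.exists():
        return json.loads(mpath.read_text())
    return {"stages": {}}


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute all stages; returns the manifest.

    A stage is skipped when its artifacts exist and were produced under the
    same config digest (resumability); deleting an intermediate artifact
    recomputes it and everything downstream.  Any stage failure aborts with
    the stage name while completed artifacts persist.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    manifest = _load_manifest(out)
    if manifest.get("config_digest") not in (None, digest):
        manifest = {"stages": {}}  # config changed: start over
    manifest.update(
        config_digest=digest, seed=config.seed, version=__version__
    )
    stale = False  # once a stage reruns, everything downstream reruns

    def stage_done(name: str, artifacts: list[Path]) -> bool:
        rec = manifest["stages"].get(name)
        return (
            not stale
            and rec is not None
            and rec.get("config_digest") == digest
            and all(a.exists() for a in artifacts)
        )

    def run_stage(name: str, artifacts: list[Path], fn):
        nonlocal stale
        if stage_done(name, artifacts):
            if verbose:
                print(f"[{name}] up to date")
            return
        t0 = time.perf_counter()
        try:
            extra = fn() or {}
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": repr(exc)}
            _write_manifest(out, manifest)
            raise PipelineError(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(dt, 3),
            "config_digest": digest,
            **extra,
        }
        stale = True
        _write_manifest(out, manifest)
        if verbose:
            print(f"[{name}] done in {dt:.1f}s {extra or ''}")

    scenes_dir = Path(config.scenes_dir)
    maps_dir = out / "maps"
    fix = read_fixation_table(config.fixations_path)
    scene_ids = sorted(fix["scene_id"].unique())
    map_paths = {sid: maps_dir / f"{sid}.npz" for sid in scene_ids}

    def do_features():
        cfg = config.feature_map_config()
        for sid in scene_ids:
            candidates = list(scenes_dir.glob(f"{sid}.*"))
            if not candidates:
                raise FileNotFoundError(f"no image for scene {sid!r} in {scenes_dir}")
            scene = read_scene_image(candidates[0], config.px_per_deg, sid)
            save_feature_maps(compute_feature_maps(scene, cfg), map_paths[sid])
        return {"n_scenes": len(scene_ids)}

    patch_path = out / "patch_features.csv"

    def do_patches():
        radius_px = px_radius_for_degrees(config.patch_radius_deg, config.px_per_deg)
        parts = []
        for sid, grp in fix.groupby("scene_id", sort=False):
            parts.append(
                patch_feature_table(grp, load_feature_maps(map_paths[sid]), radius_px)
            )
        feats = apply_edge_logit(pd.concat(parts, ignore_index=True))
        write_table(feats, patch_path)
        return {"n_fixations": len(feats)}

    triplet_paths = {t: out / f"triplets_{t}.csv" for t in config.tasks}
    control_paths = {t: out / f"control_{t}.csv" for t in config.tasks}
    audit_path = out / "exclusion_audit.json"

    def do_triplets():
        feats = pd.read_csv(patch_path)
        feats["subject_id"] = feats["subject_id"].astype(str)
        feats["scene_id"] = feats["scene_id"].astype(str)
        radius_px = px_radius_for_degrees(config.patch_radius_deg, config.px_per_deg)
        h, w = config.image_size
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        audits = {}
        counts = {}
        for task in config.tasks:
            sub = feats[feats["task"] == task]
            trip, audit = build_triplets(
                sub, config.px_per_deg, center, radius_px,
                config.min_saccade_deg, config.min_duration_ms,
                config.max_duration_ms,
            )
            ctrl = build_control_table(
                sub, config.px_per_deg, center,
                config.min_duration_ms, config.max_duration_ms,
            )
            write_table(trip, triplet_paths[task])
            write_table(ctrl, control_paths[task])
            audits[task] = audit
            counts[task] = len(trip)
        audit_path.write_text(json.dumps(audits, indent=2, sort_keys=True))
        return {"triplets": counts}

    fit_paths = {t: out / f"fit_{t}.json" for t in config.tasks}

    def do_fit():
        spec = _model_spec(config)
        info = {}
        for task in config.tasks:
            table = pd.read_csv(triplet_paths[task])
            dm = build_design(table, spec)
            fit = fit_zcplmm(dm, criterion="REML")
            r2 = r2_lmm(fit)
            fixed = fixed_effect_tests(fit)
            write_table(fixed, out / f"fixed_effects_{task}.csv")
            fit_paths[task].write_text(
                json.dumps(
                    {
                        "task": task,
                        "n_obs": fit.n_obs,
                        "criterion": fit.criterion,
                        "deviance": fit.deviance,
                        "variance_components": fit.variance_components,
                        "residual_var": fit.residual_var,
                        "marginal_r2": r2.marginal,
                        "conditional_r2": r2.conditional,
                        "n_iter": fit.n_iter,
                        "n_eval": fit.n_eval,
                        "converged": fit.converged,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            info[task] = {"n_obs": fit.n_obs, "marginal_r2": round(r2.marginal, 4)}
        return info

    report_path = out / "binned_summaries.csv"

    def do_report():
        parts = []
        for task in config.tasks:
            table = pd.read_csv(triplet_paths[task])
            table["task"] = task
            for feat in FEATURE_COLS:
                col = f"{feat}_curr"
                # discrete predictors (segment counts) can have fewer
                # distinct values than the requested quantile bins
                n_bins = min(config.n_bins, table[col].nunique())
                if n_bins < 2:
                    continue
                parts.append(binned_summary(table, col, n_bins=n_bins, by="task"))
        write_table(pd.concat(parts, ignore_index=True), report_path)

    run_stage("features", list(map_paths.values()), do_features)
    run_stage("patches", [patch_path], do_patches)
    run_stage(
        "triplets",
        list(triplet_paths.values()) + list(control_paths.values()) + [audit_path],
        do_triplets,
    )
    run_stage("fit", list(fit_paths.values()), do_fit)
    run_stage("report", [report_path], do_report)
    return manifest


def simulate_study(
    outdir,
    n_subjects: int = 24,
    n_scenes: int = 45,
    seed: int = 0,
    task: str = "memorization",
    scene_shape: tuple[int, int] = (96, 128),
    px_per_deg: float = 5.0,
) -> PipelineConfig:
    """Write a complete synthetic study: scenes (PNG), a fixation report
    (CSV), the design (JSON), the ground-truth parameters (JSON), and a
    matching pipeline config (YAML).

    Durations are drawn from the generative model given each fixation's
    realized covariates (local features plus subject/scene intercepts), and
    onsets are rebuilt from the drawn durations.
    """
    from .feature_maps import FeatureMapConfig
    from .io import write_scene_image
    from .synthetic import (
        GenerativeParams,
        ScanpathParams,
        make_design,
        make_scene,
        simulate_dataset,
    )

    outdir = Path(outdir)
    (outdir / "scenes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    params = GenerativeParams()
    sp = ScanpathParams()
    design = make_design(seed=seed, n_subjects=n_subjects, n_scenes=n_scenes)

    cfg_maps = FeatureMapConfig(ms_spatial_bandwidth=5, ms_max_iter=5)
    fmaps = {}
    for scene_id in design.scenes["scene_id"]:
        scene = make_scene(
            seed=int(rng.integers(2 ** 31)), size=scene_shape,
            px_per_deg=px_per_deg, scene_id=scene_id,
        )
        write_scene_image(scene, outdir / "scenes" / f"{scene_id}.png")
        fmaps[scene_id] = compute_feature_maps(scene, cfg_maps)

    prov = float(np.exp(params.b["1"]))
    fix = simulate_dataset(
        design, scene_shape, px_per_deg, sp, rng, task=task,
        provisional_duration_ms=prov,
    )
    radius_px = px_radius_for_degrees(1.0, px_per_deg)
    parts = []
    for sid, grp in fix.groupby("scene_id", sort=False):
        parts.append(patch_feature_table(grp, fmaps[sid], radius_px))
    feats = apply_edge_logit(pd.concat(parts, ignore_index=True))

    # per-fixation generative predictors: z-scored immediacy features plus
    # subject/scene intercepts; durations then rebuilt into onsets
    log_d = np.full(len(feats), params.b["1"])
    for feat in FEATURE_COLS:
        col = feats[feat].to_numpy(dtype=float)
        z = (col - col.mean()) / col.std(ddof=1)
        log_d += params.b.get(f"{feat}_curr", 0.0) * z
    for factor, key in (("subject_id", "subject_id:1"), ("scene_id", "scene_id:1")):
        sd = params.random_sd.get(key, 0.0)
        codes, levels = pd.factorize(feats[factor], sort=True)
        log_d += rng.normal(0.0, sd, size=len(levels))[codes]
    log_d += rng.normal(0.0, params.residual_sd, size=len(feats))
    feats["duration_ms"] = np.exp(log_d)
    sacc_ms = sp.saccade_base_ms + sp.saccade_ms_per_deg * 5.0
    feats["onset_ms"] = feats.groupby(
        ["subject_id", "task", "scene_id", "trial_index"], sort=False
    )["duration_ms"].transform(lambda d: (d + sacc_ms).cumsum() - (d + sacc_ms))

    cols = list(
        dict.fromkeys(
            [
                "subject_id", "scene_id", "task", "trial_index", "fixation_index",
                "x", "y", "duration_ms", "onset_ms", "blink", "response_time_ms",
            ]
        )
    )
    write_table(feats[cols], outdir / "fixations.csv")
    design.subjects.to_json(outdir / "design_subjects.json", orient="records", indent=2)
    design.scenes.to_json(outdir / "design_scenes.json", orient="records", indent=2)
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "b": params.b,
                "random_sd": params.random_sd,
                "residual_sd": params.residual_sd,
                "seed": seed,
            },
            indent=2,
            sort_keys=True,
        )
    )
    config = PipelineConfig(
        scenes_dir=str(outdir / "scenes"),
        fixations_path=str(outdir / "fixations.csv"),
        output_dir=str(outdir / "out"),
        px_per_deg=px_per_deg,
        image_size=scene_shape,
        tasks=(task,),
        seed=seed,
        feature_maps={"ms_spatial_bandwidth": 5, "ms_max_iter": 5},
    )
    config.to_yaml(outdir / "config.yaml")
    return config
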