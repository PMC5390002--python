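"""Synthetic study generator with known ground truth.

Emulates the study design and the statistical structure the analysis
assumes, so the whole pipeline can be exercised and validated end to end:

* a dual Latin-square design (9 groups x 8 subjects, 3 scene lists x 45
  scenes, 3 task orders) controlling which scenes a subject views in which
  task,
* synthetic scene images with controllable spatial variation in all five
  feature maps,
* scanpaths with a realistic covariate structure (central bias, direction
  persistence, roughly 5-degree median saccades),
* log-normal fixation durations drawn from a generative zcpLMM whose fixed
  effects default to the memorization-task estimates of the original
  corpus analysis, and
* a parameter-recovery harness (simulate -> full pipeline -> fit) used by
  the validation suite.

Durations are generated conditionally on the realized covariates
(locations first, durations second), which makes the generating
coefficients recoverable by construction; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .feature_maps import FeatureMapConfig, SceneImage, compute_feature_maps
from .lmm import (
    FULL_FIXED_TERMS,
    DesignMatrices,
    ModelSpec,
    build_design,
    fit_zcplmm,
    r2_lmm,
)
from .patch_stats import apply_edge_logit, patch_feature_table, px_radius_for_degrees
from .triplets import build_triplets

__all__ = [
    "TASKS",
    "TASK_ORDERS",
    "MEMORIZATION_DEFAULT_B",
    "GenerativeParams",
    "ScanpathParams",
    "DesignAssignment",
    "make_design",
    "make_scene",
    "simulate_scanpath",
    "simulate_durations",
    "simulate_dataset",
    "default_recovery_spec",
    "run_analysis_pipeline",
    "recovery_experiment",
]

TASKS = ("memorization", "preference", "search")

#: the three task-block orders used across subject groups
TASK_ORDERS = (
    ("search", "memorization", "preference"),
    ("preference", "search", "memorization"),
    ("memorization", "preference", "search"),
)

#: generative fixed effects on the log-ms scale (memorization-task defaults)
MEMORIZATION_DEFAULT_B = {
    "1": 5.534,
    "luminance_curr": -0.014,
    "luminance_prev": 0.004,
    "luminance_next": -0.006,
    "contrast_curr": -0.017,
    "contrast_prev": -0.001,
    "contrast_next": 0.007,
    "edge_density_curr": 0.021,
    "edge_density_prev": 0.004,
    "edge_density_next": -0.005,
    "clutter_curr": 0.021,
    "clutter_prev": -0.009,
    "clutter_next": -0.008,
    "n_segments_curr": 0.023,
    "n_segments_prev": 0.004,
    "n_segments_next": -0.003,
    "sacc_amp_prev": 0.028,
    "sacc_amp_prev_sq": -0.011,
    "sacc_amp_next": -0.025,
    "delta_angle": 0.065,
    "viewing_time": 0.040,
    "viewing_time_sq": -0.030,
    "central_distance": 0.004,
}


def _default_random_sd() -> dict[str, float]:
    # intercept SDs dominate, giving a conditional-minus-marginal R^2 gap
    # of roughly 10-15 percentage points; a few modest slopes exercise the
    # slope-aware machinery
    return {
        "subject_id:1": 0.12,
        "scene_id:1": 0.08,
        "subject_id:sacc_amp_prev": 0.02,
        "subject_id:delta_angle": 0.02,
        "subject_id:viewing_time": 0.02,
        "scene_id:contrast_curr": 0.01,
        "scene_id:edge_density_curr": 0.01,
    }


@dataclass
class GenerativeParams:
    """True parameters of the generative duration model (log-ms scale)."""

    b: dict[str, float] = field(default_factory=lambda: dict(MEMORIZATION_DEFAULT_B))
    random_sd: dict[str, float] = field(default_factory=_default_random_sd)
    residual_sd: float = 0.40

    def __post_init__(self):
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be > 0")
        if any(sd < 0 for sd in self.random_sd.values()):
            raise ValueError("random-effect SDs must be >= 0")

    def null_effects(self) -> "GenerativeParams":
        """Copy with every fixed effect except the intercept set to zero."""
        b0 = {k: (v if k == "1" else 0.0) for k, v in self.b.items()}
        return GenerativeParams(
            b=b0, random_sd=dict(self.random_sd), residual_sd=self.residual_sd
        )


@dataclass
class ScanpathParams:
    """Parameters of the scanpath simulator.

    Saccade amplitudes are log-normal with the given median (degrees);
    direction persistence is a von-Mises concentration around the previous
    saccade direction; central bias pulls each landing point a fraction of
    the way back toward the image center.  Trials last 8 s.
    """

    saccade_median_deg: float = 5.0
    saccade_log_sd: float = 0.45
    momentum_kappa: float = 1.5
    central_bias: float = 0.25
    blink_rate: float = 0.02
    trial_duration_ms: float = 8000.0
    max_fixations: int = 60
    saccade_base_ms: float = 20.0
    saccade_ms_per_deg: float = 2.0

    def __post_init__(self):
        if not 0 <= self.blink_rate <= 1:
            raise ValueError("blink_rate must lie in [0, 1]")
        if not 0 <= self.central_bias <= 1:
            raise ValueError("central_bias must lie in [0, 1]")
        if not self.saccade_median_deg > 0:
            raise ValueError("saccade amplitudes must be > 0")


@dataclass
class DesignAssignment:
    """Subject-group/scene-list allocation of the dual Latin square."""

    subjects: pd.DataFrame  # subject_id, subject_group, task_order, list_<task>
    scenes: pd.DataFrame  # scene_id, scene_list

    def scenes_for(self, subject_id: str, task: str) -> list[str]:
        row = self.subjects.set_index("subject_id").loc[subject_id]
        lst = int(row[f"list_{task}"])
        return self.scenes.loc[self.scenes["scene_list"] == lst, "scene_id"].tolist()


def make_design(
    seed: int = 0, n_subjects: int = 72, n_scenes: int = 135
) -> DesignAssignment:
    """Allocate subjects to the 9 cells of the dual Latin square.

    Nine groups (3 task orders x 3 list rotations) of subjects; scenes are
    split into three lists which rotate over tasks across groups.  At the
    full size (72 subjects, 135 scenes) every subject sees each scene
    exactly once, 24 subjects share any list-by-task combination, and 8
    share a list-by-task-by-order cell.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_subjects))
    subject_ids = [f"s{i + 1:0{width}d}" for i in range(n_subjects)]
    rng.shuffle(subject_ids)
    rows = []
    for i, sid in enumerate(subject_ids):
        cell = i % 9
        oi, ri = divmod(cell, 3)
        row = {
            "subject_id": sid,
            "subject_group": cell + 1,
            "task_order": "-".join(TASK_ORDERS[oi]),
        }
        for ti, task in enumerate(TASKS):
            row[f"list_{task}"] = (ti + ri) % 3 + 1
        rows.append(row)
    subjects = (
        pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
    )

    swidth = len(str(n_scenes))
    scene_ids = [f"scene{j + 1:0{swidth}d}" for j in range(n_scenes)]
    rng.shuffle(scene_ids)
    scenes = pd.DataFrame(
        {
            "scene_id": scene_ids,
            "scene_list": [j % 3 + 1 for j in range(n_scenes)],
        }
    ).sort_values("scene_id").reset_index(drop=True)
    return DesignAssignment(subjects=subjects, scenes=scenes)


def make_scene(
    seed: int,
    size: tuple[int, int] = (96, 128),
    px_per_deg: float = 5.0,
    texture_spec: str = "mixed",
    scene_id: str | None = None,
) -> SceneImage:
    """Generate a synthetic scene image.

    ``mixed`` scenes composite a smooth luminance gradient, solid-color
    regions, and band-limited noise patches, so that all five feature maps
    vary spatially.  ``flat`` is a constant image; ``halves`` has two
    luminance levels with a vertical divide.  Deterministic given the seed.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    sid = scene_id or f"scene-{texture_spec}-{seed}"
    if texture_spec == "flat":
        img = np.full((h, w, 3), 128.0)
    elif texture_spec == "halves":
        img = np.full((h, w, 3), 60.0)
        img[:, w // 2 :] = 180.0
    elif texture_spec == "mixed":
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (np.cos(phi) * xx / w + np.sin(phi) * yy / h)
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
        c0 = rng.uniform(40, 120, size=3)
        c1 = rng.uniform(130, 215, size=3)
        img = c0[None, None] + ramp[..., None] * (c1 - c0)[None, None]
        for _ in range(int(rng.integers(6, 12))):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry, rx = rng.uniform(h / 16, h / 4), rng.uniform(w / 16, w / 4)
            region = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            img[region] = rng.uniform(20, 235, size=3)
        for _ in range(int(rng.integers(2, 5))):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry, rx = rng.uniform(h / 12, h / 5), rng.uniform(w / 12, w / 5)
            region = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            noise = ndimage.gaussian_filter(
                rng.normal(0, 1, size=(h, w, 3)), (rng.uniform(0.5, 1.5),) * 2 + (0,)
            )
            amp = rng.uniform(40, 90)
            img[region] = np.clip(img[region] + amp * noise[region], 0, 255)
    else:
        raise ValueError(f"unknown texture_spec {texture_spec!r}")
    return SceneImage(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        px_per_deg=px_per_deg,
        scene_id=sid,
    )


def _reflect(p: float, lo: float, hi: float) -> float:
    period = 2.0 * (hi - lo)
    q = (p - lo) % period
    return lo + min(q, period - q)


def simulate_scanpath(
    shape: tuple[int, int],
    px_per_deg: float,
    params: ScanpathParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one trial's fixation locations and blink flags.

    Sequential model: each saccade direction is von-Mises distributed
    around the previous direction (saccadic momentum), amplitudes are
    log-normal, the landing point is pulled a fraction ``central_bias``
    toward the image center, and out-of-bounds points reflect at the image
    border.  Onsets and durations are filled in later by the duration
    model.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    x = cx + rng.normal(0, 0.5 * px_per_deg)
    y = cy + rng.normal(0, 0.5 * px_per_deg)
    theta = rng.uniform(0, 2 * np.pi)
    xs, ys = [x], [y]
    for _ in range(params.max_fixations - 1):
        theta = rng.vonmises(theta, params.momentum_kappa)
        amp_deg = np.exp(
            rng.normal(np.log(params.saccade_median_deg), params.saccade_log_sd)
        )
        step = amp_deg * px_per_deg
        nx = x + step * np.cos(theta)
        ny = y + step * np.sin(theta)
        nx += params.central_bias * (cx - nx)
        ny += params.central_bias * (cy - ny)
        nx = _reflect(nx, 0.0, w - 1.0)
        ny = _reflect(ny, 0.0, h - 1.0)
        # momentum follows the realized movement direction
        if np.hypot(nx - x, ny - y) > 0:
            theta = np.arctan2(ny - y, nx - x)
        x, y = nx, ny
        xs.append(x)
        ys.append(y)
    blink = rng.random(len(xs)) < params.blink_rate
    return pd.DataFrame(
        {
            "fixation_index": np.arange(1, len(xs) + 1),
            "x": xs,
            "y": ys,
            "blink": blink,
        }
    )


def simulate_durations(
    dm: DesignMatrices, params: GenerativeParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw fixation durations (ms) from the generative zcpLMM.

    log d = X b + sum_k Z_k u_k + eps with independent normal random
    effects per component and residual; unnamed terms/components default to
    zero.  Requires X standardized exactly as the analysis standardizes it,
    which holds when ``dm`` comes from :func:`fixdur.lmm.build_design` on
    the realized analysis table.
    """
    b_vec = np.array([params.b.get(t, 0.0) for t in dm.fixed_names])
    log_d = dm.X @ b_vec
    for name, sl in zip(dm.component_names, dm.component_slices):
        sd = params.random_sd.get(name, 0.0)
        if sd > 0:
            m = sl.stop - sl.start
            u = rng.normal(0.0, sd, size=m)
            log_d = log_d + dm.Z[:, sl] @ u
    log_d = log_d + rng.normal(0.0, params.residual_sd, size=dm.n_obs)
    return np.exp(log_d)


def simulate_dataset(
    design: DesignAssignment,
    scene_shape: tuple[int, int],
    px_per_deg: float,
    scanpath_params: ScanpathParams,
    rng: np.random.Generator,
    task: str = "memorization",
    provisional_duration_ms: float = 253.0,
) -> pd.DataFrame:
    """Simulate fixation reports for one task of the design.

    Scanpath locations are generated per trial; durations are provisional
    constants (the generative intercept's scale) used to lay out onsets,
    validity windows, and the viewing-time covariate.  The actual response
    durations are drawn later, conditionally on the realized covariates.
    """
    rows = []
    for _, subj in design.subjects.iterrows():
        sid = subj["subject_id"]
        scene_ids = design.scenes.loc[
            design.scenes["scene_list"] == int(subj[f"list_{task}"]), "scene_id"
        ]
        for trial, scene_id in enumerate(scene_ids, start=1):
            path = simulate_scanpath(scene_shape, px_per_deg, scanpath_params, rng)
            amp_deg = np.concatenate(
                [
                    [0.0],
                    np.hypot(np.diff(path["x"]), np.diff(path["y"])) / px_per_deg,
                ]
            )
            sacc_ms = (
                scanpath_params.saccade_base_ms
                + scanpath_params.saccade_ms_per_deg * amp_deg
            )
            onset = np.cumsum(provisional_duration_ms + sacc_ms) - (
                provisional_duration_ms + sacc_ms[0]
            )
            keep = onset < scanpath_params.trial_duration_ms
            path = path.loc[keep].copy()
            path["onset_ms"] = onset[keep]
            path["duration_ms"] = provisional_duration_ms
            path["subject_id"] = sid
            path["scene_id"] = scene_id
            path["task"] = task
            path["trial_index"] = trial
            path["response_time_ms"] = np.nan
            rows.append(path)
    return pd.concat(rows, ignore_index=True)


def default_recovery_spec() -> ModelSpec:
    """Analysis model of the recovery harness: all 23 fixed effects plus
    the seven default generative variance components."""
    return ModelSpec(
        fixed_terms=tuple(FULL_FIXED_TERMS),
        random={
            "subject_id": ("1", "sacc_amp_prev", "delta_angle", "viewing_time"),
            "scene_id": ("1", "contrast_curr", "edge_density_curr"),
        },
    )


def run_analysis_pipeline(
    fixations: pd.DataFrame,
    feature_maps: dict,
    px_per_deg: float,
    scene_shape: tuple[int, int],
    radius_deg: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Patch statistics -> edge-density logit -> triplet table + audit."""
    radius_px = px_radius_for_degrees(radius_deg, px_per_deg)
    parts = []
    for scene_id, grp in fixations.groupby("scene_id", sort=False):
        parts.append(patch_feature_table(grp, feature_maps[scene_id], radius_px))
    feats = pd.concat(parts, ignore_index=True)
    feats = apply_edge_logit(feats)
    h, w = scene_shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    return build_triplets(feats, px_per_deg, center, radius_px)


def recovery_experiment(
    params: GenerativeParams | None = None,
    n_subjects: int = 24,
    n_scenes: int = 45,
    n_reps: int = 100,
    seed: int = 0,
    spec: ModelSpec | None = None,
    scanpath_params: ScanpathParams | None = None,
    scene_shape: tuple[int, int] = (96, 128),
    px_per_deg: float = 5.0,
    task: str = "memorization",
) -> dict:
    """Simulate -> run full pipeline -> fit, over replicates.

    Scenes, feature maps and the design are generated once; every replicate
    re-simulates scanpaths, rebuilds the triplet table and design matrices
    from scratch, draws durations from the generative model, and refits.
    Per replicate and per fixed effect, records the estimation error, the
    95%-interval coverage of the truth, sign agreement, and significance
    flags; fit failures are logged and skipped.
    """
    params = params or GenerativeParams()
    spec = spec or default_recovery_spec()
    sp = scanpath_params or ScanpathParams()
    master = np.random.default_rng(seed)

    design = make_design(
        seed=int(master.integers(2 ** 31)), n_subjects=n_subjects, n_scenes=n_scenes
    )
    cfg = FeatureMapConfig(ms_spatial_bandwidth=5, ms_max_iter=5)
    fmaps = {}
    for j, scene_id in enumerate(design.scenes["scene_id"]):
        scene = make_scene(
            seed=int(master.integers(2 ** 31)),
            size=scene_shape,
            px_per_deg=px_per_deg,
            scene_id=scene_id,
        )
        fmaps[scene_id] = compute_feature_maps(scene, cfg)

    b_true = {t: params.b.get(t, 0.0) for t in spec.fixed_terms}
    records = []
    failures = []
    r2s = []
    prov_ms = float(np.exp(params.b.get("1", 5.534)))
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + 1_000_003 * (rep + 1))
        fixations = simulate_dataset(
            design, scene_shape, px_per_deg, sp, rng, task=task,
            provisional_duration_ms=prov_ms,
        )
        triplets, _ = run_analysis_pipeline(
            fixations, fmaps, px_per_deg, scene_shape
        )
        dm = build_design(triplets, spec)
        dm.y = np.log(simulate_durations(dm, params, rng))
        try:
            fit = fit_zcplmm(dm, criterion="REML")
        except Exception as exc:  # noqa: BLE001 - per-replicate logging
            failures.append({"rep": rep, "error": repr(exc)})
            continue
        r2 = r2_lmm(fit)
        r2s.append((r2.marginal, r2.conditional))
        for j, term in enumerate(fit.fixed_names):
            bt = b_true[term]
            records.append(
                {
                    "rep": rep,
                    "term": term,
                    "b_true": bt,
                    "b_hat": fit.b[j],
                    "se": fit.se[j],
                    "error": fit.b[j] - bt,
                    "covered": abs(fit.b[j] - bt) <= 1.96 * fit.se[j],
                    "significant": abs(fit.t[j]) > 1.96,
                    "sign_match": np.sign(fit.b[j]) == np.sign(bt),
                    "n_obs": fit.n_obs,
                }
            )
    per_rep = pd.DataFrame(records)
    summary = (
        per_rep.groupby("term")
        .agg(
            b_true=("b_true", "first"),
            mean_b_hat=("b_hat", "mean"),
            mean_error=("error", "mean"),
            coverage=("covered", "mean"),
            sig_rate=("significant", "mean"),
            sign_rate=("sign_match", "mean"),
        )
        .reindex(list(spec.fixed_terms))
    )
    nonzero = [t for t in spec.fixed_terms if t != "1" and b_true[t] != 0.0]
    zero = [t for t in spec.fixed_terms if t != "1" and b_true[t] == 0.0]
    r2_arr = np.array(r2s) if r2s else np.zeros((0, 2))
    return {
        "summary": summary,
        "records": per_rep,
        "failures": failures,
        "coverage_by_term": summary["coverage"],
        "overall_coverage": float(per_rep["covered"].mean()) if len(per_rep) else np.nan,
        "type1_rate": float(
            per_rep[per_rep["term"].isin(zero)]["significant"].mean()
        )
        if zero
        else np.nan,
        "nonzero_terms": nonzero,
        "zero_terms": zero,
        "mean_marginal_r2": float(r2_arr[:, 0].mean()) if len(r2_arr) else np.nan,
        "mean_conditional_r2": float(r2_arr[:, 1].mean()) if len(r2_arr) else np.nan,
        "n_reps_completed": int(per_rep["rep"].nunique()) if len(per_rep) else 0,
        "mean_n_obs": float(per_rep["n_obs"].mean()) if len(per_rep) else np.nan,
    }
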