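"""Fixation-triplet construction and the control-analysis table.

The response analyzed is the (log) duration of the middle fixation *n* of a
triplet (n-1, n, n+1) of consecutive fixations.  Triplets carry the five
patch statistics at all three locations plus oculomotor and spatiotemporal
covariates.  Exclusion rules:

* first and last fixation of a trial are never analyzed,
* fixation durations must lie in [50, 1000] ms,
* blink-adjacent fixations invalidate the triplet,
* during search, only fixations up to the button press are analyzed,
* the incoming and outgoing saccades must exceed 2 degrees, and the three
  1-degree patch masks must be pairwise disjoint.

The control analysis keeps one row per valid fixation regardless of the
amplitudes of its flanking saccades (immediacy effects only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FEATURE_COLS = ["luminance", "contrast", "edge_density", "clutter", "n_segments"]
POSITIONS = ["curr", "prev", "next"]

__all__ = [
    "FEATURE_COLS",
    "POSITIONS",
    "saccade_amplitude",
    "delta_angle",
    "central_distance",
    "viewing_time",
    "validate_fixations",
    "build_triplets",
    "build_control_table",
]


def saccade_amplitude(fix_a, fix_b, px_per_deg: float) -> float:
    """Amplitude in degrees of the saccade between two consecutive fixations.

    ``fix_a`` and ``fix_b`` are mappings with keys ``x``, ``y`` and
    ``fixation_index``; the indices must be consecutive.
    """
    if abs(int(fix_b["fixation_index"]) - int(fix_a["fixation_index"])) != 1:
        raise ValueError("saccade amplitude requires consecutive fixations")
    return float(
        np.hypot(fix_b["x"] - fix_a["x"], fix_b["y"] - fix_a["y"]) / px_per_deg
    )


def delta_angle(fix_prev, fix_n, fix_next) -> float:
    """Absolute angular difference (degrees, [0, 180]) between the incoming
    and outgoing saccade directions; 0 continues the trajectory, 180 is a
    complete reversal."""
    v1 = np.array([fix_n["x"] - fix_prev["x"], fix_n["y"] - fix_prev["y"]], float)
    v2 = np.array([fix_next["x"] - fix_n["x"], fix_next["y"] - fix_n["y"]], float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length saccade vector")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def central_distance(fix, image_center_xy, px_per_deg: float) -> float:
    """Euclidean distance (degrees) of a fixation from the image center."""
    return float(
        np.hypot(fix["x"] - image_center_xy[0], fix["y"] - image_center_xy[1])
        / px_per_deg
    )


def viewing_time(fix) -> float:
    """Time (ms) from scene onset to the end of the fixation."""
    return float(fix["onset_ms"] + fix["duration_ms"])


TRIAL_KEYS = ["subject_id", "task", "scene_id", "trial_index"]


def validate_fixations(
    fixations: pd.DataFrame,
    min_duration_ms: float = 50.0,
    max_duration_ms: float = 1000.0,
) -> pd.DataFrame:
    """Append ``valid`` and ``invalid_reason`` columns (trial-context aware).

    Reasons (first matching, in order): ``boundary`` (first/last fixation of
    the trial), ``too_short``, ``too_long``, ``blink``, ``after_response``
    (search only: fixation ends after the button press).
    """
    df = fixations.sort_values(TRIAL_KEYS + ["fixation_index"]).reset_index(drop=True)
    grp = df.groupby(TRIAL_KEYS, sort=False)["fixation_index"]
    first = grp.transform("min")
    last = grp.transform("max")
    reason = np.full(len(df), "", dtype=object)

    boundary = (df["fixation_index"] == first) | (df["fixation_index"] == last)
    too_short = df["duration_ms"] < min_duration_ms
    too_long = df["duration_ms"] > max_duration_ms
    blink = df.get("blink", pd.Series(False, index=df.index)).astype(bool)
    if "response_time_ms" in df.columns:
        rt = pd.to_numeric(df["response_time_ms"], errors="coerce")
        after = (
            (df["task"] == "search")
            & rt.notna()
            & (df["onset_ms"] + df["duration_ms"] > rt)
        )
    else:
        after = pd.Series(False, index=df.index)

    for flag, name in [
        (boundary, "boundary"),
        (too_short, "too_short"),
        (too_long, "too_long"),
        (blink, "blink"),
        (after, "after_response"),
    ]:
        hit = flag.to_numpy() & (reason == "")
        reason[hit] = name
    df["invalid_reason"] = reason
    df["valid"] = reason == ""
    return df


def _trial_geometry(tr: pd.DataFrame, px_per_deg: float, center_xy):
    x = tr["x"].to_numpy(float)
    y = tr["y"].to_numpy(float)
    dx = np.diff(x)
    dy = np.diff(y)
    amp = np.hypot(dx, dy) / px_per_deg  # amp[i] = saccade i -> i+1
    cdist = np.hypot(x - center_xy[0], y - center_xy[1]) / px_per_deg
    return x, y, amp, cdist


def build_triplets(
    fixations: pd.DataFrame,
    px_per_deg: float,
    image_center_xy: tuple[float, float],
    radius_px: float,
    min_saccade_deg: float = 2.0,
    min_duration_ms: float = 50.0,
    max_duration_ms: float = 1000.0,
) -> tuple[pd.DataFrame, dict]:
    """Build the triplet analysis table from a patch-feature fixation table.

    ``fixations`` must contain the trial keys, geometry/timing columns and
    the five patch-feature columns.  Returns the triplet table (one row per
    retained triplet, features suffixed ``_curr``/``_prev``/``_next``) and
    an exclusion audit with counts per reason.

    A fixation may serve all three roles in successive triplets; a run of
    five valid fixations yields three triplets.
    """
    df = validate_fixations(fixations, min_duration_ms, max_duration_ms)
    audit: dict[str, int] = {
        r: int((df["invalid_reason"] == r).sum())
        for r in ["boundary", "too_short", "too_long", "blink", "after_response"]
    }
    audit["candidate_triplets"] = 0
    audit["removed_invalid_fixation"] = 0
    audit["removed_saccade_amplitude"] = 0
    audit["removed_patch_overlap"] = 0

    rows = []
    for keys, tr in df.groupby(TRIAL_KEYS, sort=False):
        tr = tr.sort_values("fixation_index")
        k = len(tr)
        if k < 3:
            continue
        x, y, amp, cdist = _trial_geometry(tr, px_per_deg, image_center_xy)
        valid = tr["valid"].to_numpy()
        vt = (tr["onset_ms"] + tr["duration_ms"]).to_numpy(float)
        for i in range(1, k - 1):
            audit["candidate_triplets"] += 1
            if not (valid[i - 1] and valid[i] and valid[i + 1]):
                audit["removed_invalid_fixation"] += 1
                continue
            if amp[i - 1] <= min_saccade_deg or amp[i] <= min_saccade_deg:
                audit["removed_saccade_amplitude"] += 1
                continue
            # flanking patches are disjoint by the amplitude rule; the
            # n-1 vs n+1 pair must be checked explicitly (return saccades)
            d_pn = np.hypot(x[i + 1] - x[i - 1], y[i + 1] - y[i - 1])
            if d_pn <= 2 * radius_px:
                audit["removed_patch_overlap"] += 1
                continue
            v1 = np.array([x[i] - x[i - 1], y[i] - y[i - 1]])
            v2 = np.array([x[i + 1] - x[i], y[i + 1] - y[i]])
            cosang = np.clip(
                v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
            )
            row = dict(zip(TRIAL_KEYS, keys))
            row.update(
                fixation_index=int(tr["fixation_index"].iloc[i]),
                duration_ms=float(tr["duration_ms"].iloc[i]),
                log_duration=float(np.log(tr["duration_ms"].iloc[i])),
                sacc_amp_prev=float(amp[i - 1]),
                sacc_amp_next=float(amp[i]),
                delta_angle=float(np.degrees(np.arccos(cosang))),
                central_distance=float(cdist[i]),
                viewing_time=float(vt[i]),
            )
            for feat in FEATURE_COLS:
                col = feat if feat in tr.columns else None
                if col is None:
                    raise KeyError(f"fixation table lacks feature column {feat!r}")
                row[f"{feat}_curr"] = float(tr[col].iloc[i])
                row[f"{feat}_prev"] = float(tr[col].iloc[i - 1])
                row[f"{feat}_next"] = float(tr[col].iloc[i + 1])
            rows.append(row)
    audit["triplets_kept"] = len(rows)
    cols = (
        TRIAL_KEYS
        + ["fixation_index", "duration_ms", "log_duration"]
        + [f"{f}_{p}" for f in FEATURE_COLS for p in POSITIONS]
        + ["sacc_amp_prev", "sacc_amp_next", "delta_angle", "central_distance",
           "viewing_time"]
    )
    table = pd.DataFrame(rows, columns=cols)
    return table, audit


def build_control_table(
    fixations: pd.DataFrame,
    px_per_deg: float,
    image_center_xy: tuple[float, float],
    min_duration_ms: float = 50.0,
    max_duration_ms: float = 1000.0,
) -> pd.DataFrame:
    """Control-analysis table: every valid fixation, saccades of any length.

    One row per valid focal fixation (duration, blink, boundary and
    button-press filters still apply); the incoming and outgoing saccades
    may have any amplitude, so immediacy effects can be tested on a much
    larger dataset with no lag/successor terms.  Feature columns keep the
    ``_curr`` suffix so model specs are shared with the triplet table.
    """
    df = validate_fixations(fixations, min_duration_ms, max_duration_ms)
    rows = []
    for keys, tr in df.groupby(TRIAL_KEYS, sort=False):
        tr = tr.sort_values("fixation_index")
        k = len(tr)
        if k < 3:
            continue
        x, y, amp, cdist = _trial_geometry(tr, px_per_deg, image_center_xy)
        valid = tr["valid"].to_numpy()
        vt = (tr["onset_ms"] + tr["duration_ms"]).to_numpy(float)
        for i in range(1, k - 1):
            if not valid[i]:
                continue
            if amp[i - 1] == 0 or amp[i] == 0:
                continue  # degenerate saccade vector: direction undefined
            v1 = np.array([x[i] - x[i - 1], y[i] - y[i - 1]])
            v2 = np.array([x[i + 1] - x[i], y[i + 1] - y[i]])
            cosang = np.clip(
                v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
            )
            row = dict(zip(TRIAL_KEYS, keys))
            row.update(
                fixation_index=int(tr["fixation_index"].iloc[i]),
                duration_ms=float(tr["duration_ms"].iloc[i]),
                log_duration=float(np.log(tr["duration_ms"].iloc[i])),
                sacc_amp_prev=float(amp[i - 1]),
                sacc_amp_next=float(amp[i]),
                delta_angle=float(np.degrees(np.arccos(cosang))),
                central_distance=float(cdist[i]),
                viewing_time=float(vt[i]),
            )
            for feat in FEATURE_COLS:
                row[f"{feat}_curr"] = float(tr[feat].iloc[i])
            rows.append(row)
    cols = (
        TRIAL_KEYS
        + ["fixation_index", "duration_ms", "log_duration"]
        + [f"{f}_curr" for f in FEATURE_COLS]
        + ["sacc_amp_prev", "sacc_amp_next", "delta_angle", "central_distance",
           "viewing_time"]
    )
    return pd.DataFrame(rows, columns=cols)
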