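"""Descriptive and model-based summaries.

Two kinds of figures back the analysis: quantile-binned mean fixation
durations with within-subject (Cousineau) standard errors, and predicted
partial-effect curves extracted from fitted mixed models (keep a set of
fixed effects, remove everything else including the random effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import FitResult

__all__ = [
    "quantile_bins",
    "within_subject_se",
    "binned_summary",
    "partial_effects",
    "partial_fitted",
    "PartialEffectCurve",
    "plot_binned_summary",
    "plot_partial_effect",
]


def quantile_bins(values, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Assign observations to ``n_bins`` approximately equal-sized quantile
    categories of a continuous variable.

    Ties are broken by stable order (sort-and-slice), so group sizes differ
    by at most one.  Returns ``(assignment, bin_means)`` where the bin
    center is the mean of its members.
    """
    vals = np.asarray(values, dtype=np.float64)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.unique(vals).size < n_bins:
        raise ValueError("fewer distinct values than bins")
    order = np.argsort(vals, kind="stable")
    assignment = np.empty(len(vals), dtype=int)
    edges = np.linspace(0, len(vals), n_bins + 1).round().astype(int)
    for b in range(n_bins):
        assignment[order[edges[b] : edges[b + 1]]] = b
    means = np.array([vals[assignment == b].mean() for b in range(n_bins)])
    return assignment, means


def within_subject_se(
    table: pd.DataFrame,
    subject_col: str = "subject_id",
    bin_col: str = "bin",
    value_col: str = "duration_ms",
) -> pd.Series:
    """Within-subject standard error per bin (Cousineau normalization).

    Each observation is recentered, y' = y - subject mean + grand mean,
    which removes between-subject offsets; the SE per bin is the SD across
    the subjects' normalized bin means divided by sqrt(number of subjects
    contributing to the bin).
    """
    df = table[[subject_col, bin_col, value_col]].copy()
    grand = df[value_col].mean()
    subj_mean = df.groupby(subject_col)[value_col].transform("mean")
    df["_norm"] = df[value_col] - subj_mean + grand
    cell = df.groupby([subject_col, bin_col])["_norm"].mean().reset_index()
    out = cell.groupby(bin_col)["_norm"].agg(
        lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    )
    if df[subject_col].nunique() == 1:
        warnings.warn("single subject: within-subject SEs are 0", UserWarning,
                      stacklevel=2)
        out[:] = 0.0
    out.name = "within_subject_se"
    return out


def binned_summary(
    table: pd.DataFrame,
    predictor: str,
    n_bins: int = 10,
    value_col: str = "duration_ms",
    subject_col: str = "subject_id",
    by: str | None = "task",
) -> pd.DataFrame:
    """Quantile-binned means of the response with within-subject SEs.

    One row per (task, bin): bin center (mean of the predictor within the
    bin), mean response, Cousineau SE, and the bin size.
    """
    parts = []
    groups = table.groupby(by, sort=False) if by and by in table.columns else [
        (None, table)
    ]
    for key, g in groups:
        g = g.reset_index(drop=True)
        assignment, centers = quantile_bins(g[predictor], n_bins)
        g = g.assign(bin=assignment)
        se = within_subject_se(g, subject_col, "bin", value_col)
        summ = g.groupby("bin").agg(
            mean_response=(value_col, "mean"), n=(value_col, "size")
        )
        summ["bin_center"] = centers
        summ["se"] = se
        summ["predictor"] = predictor
        if key is not None:
            summ[by] = key
        parts.append(summ.reset_index())
    return pd.concat(parts, ignore_index=True)


@dataclass
class PartialEffectCurve:
    """Predicted partial effect of one predictor on log duration."""

    predictor: str
    grid: np.ndarray  # z-units
    effect: np.ndarray  # predicted log-duration partial effect
    lower: np.ndarray  # 95% bounds
    upper: np.ndarray

    def __post_init__(self):
        if np.any(self.lower > self.effect) or np.any(self.upper < self.effect):
            raise ValueError("interval must contain the point prediction")


def partial_fitted(fit: FitResult, keep_fixed: set[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation split of the fit into kept and removed parts.

    ``kept`` is the prediction from the kept fixed effects only; ``removed``
    collects the remaining fixed effects, all random effects, and the
    residuals, so ``kept + removed`` reproduces the observed response
    exactly.
    """
    dm = fit.design
    if dm is None:
        raise ValueError("fit carries no design")
    unknown = keep_fixed - set(fit.fixed_names)
    if unknown:
        raise KeyError(f"unknown fixed terms: {sorted(unknown)}")
    keep_idx = [j for j, name in enumerate(fit.fixed_names) if name in keep_fixed]
    drop_idx = [j for j, name in enumerate(fit.fixed_names) if name not in keep_fixed]
    kept = dm.X[:, keep_idx] @ fit.b[keep_idx]
    random_part = fit.fitted - dm.X @ fit.b
    removed = dm.X[:, drop_idx] @ fit.b[drop_idx] + random_part + fit.residuals
    return kept, removed


def partial_effects(
    fit: FitResult,
    predictor: str,
    grid: np.ndarray | None = None,
    keep_fixed: set[str] | None = None,
) -> PartialEffectCurve:
    """Partial-effect curve of one predictor from a fitted model.

    The curve is intercept + the kept fixed effects evaluated on a grid in
    z-units (all other predictors at their mean, i.e. 0); between-subject
    and between-item variance is removed by construction.  The 95% band
    uses the normal approximation with the fixed-effect covariance of the
    kept terms.
    """
    if keep_fixed is None:
        keep_fixed = {"1", predictor}
    unknown = keep_fixed - set(fit.fixed_names)
    if unknown:
        raise KeyError(f"unknown fixed terms: {sorted(unknown)}")
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 41)
    grid = np.asarray(grid, dtype=np.float64)

    G = np.zeros((len(grid), len(fit.fixed_names)))
    for j, name in enumerate(fit.fixed_names):
        if name not in keep_fixed:
            continue
        if name == "1":
            G[:, j] = 1.0
        elif name == predictor:
            G[:, j] = grid
        elif name.endswith("_sq") and name[: -len("_sq")] == predictor:
            G[:, j] = grid ** 2
        # other kept terms stay at their mean (0 in z-units)
    effect = G @ fit.b
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, fit.cov_b, G))
    return PartialEffectCurve(
        predictor=predictor,
        grid=grid,
        effect=effect,
        lower=effect - 1.96 * se,
        upper=effect + 1.96 * se,
    )


def plot_binned_summary(summary: pd.DataFrame, ax=None, by: str = "task"):
    """Render a binned-means panel: one line per task with error bars.

    Expects the output of :func:`binned_summary`; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    styles = {"memorization": "-.", "preference": "-", "search": "--"}
    groups = summary.groupby(by, sort=False) if by in summary.columns else [
        (None, summary)
    ]
    for key, g in groups:
        g = g.sort_values("bin_center")
        ax.errorbar(
            g["bin_center"], g["mean_response"], yerr=g["se"],
            linestyle=styles.get(key, "-"), marker="o", capsize=2, label=key,
        )
    ax.set_xlabel(str(summary["predictor"].iloc[0]))
    ax.set_ylabel("mean fixation duration (ms)")
    if by in summary.columns:
        ax.legend()
    return ax


def plot_partial_effect(curve: PartialEffectCurve, ax=None, label=None):
    """Render a partial-effect curve with its 95% band; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.grid, curve.effect, label=label)
    ax.fill_between(curve.grid, curve.lower, curve.upper, alpha=0.25)
    ax.set_xlabel(f"{curve.predictor} (z units)")
    ax.set_ylabel("predicted log fixation duration")
    if label:
        ax.legend()
    return ax
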