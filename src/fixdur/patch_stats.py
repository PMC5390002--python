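"""Local image statistics in circular foveal patches around fixations.

Patches approximate foveal vision: circles with a 1-degree radius centered
on each fixation location.  Five statistics are extracted per patch:

* mean normalized luminance,
* RMS contrast (patch luminance SD divided by mean image luminance),
* edge density (proportion of edge pixels; analyzed after a logit transform),
* mean clutter,
* number of distinct segments intersecting the patch.

Geometry uses pixel centers: a pixel belongs to the patch iff its center
lies within the radius.  Patches that extend past the image border are
clipped to in-bounds pixels and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_maps import FeatureMapSet

__all__ = [
    "PatchFeatures",
    "circular_mask",
    "px_radius_for_degrees",
    "patch_luminance",
    "patch_contrast",
    "patch_edge_density",
    "logit_transform",
    "patch_clutter",
    "patch_segment_count",
    "patch_overlap_fraction",
    "patch_feature_table",
    "apply_edge_logit",
]


class EmptyPatchError(ValueError):
    """The circular patch contains no in-bounds pixels (invalid fixation)."""


@dataclass(frozen=True)
class PatchFeatures:
    """The five local statistics of one circular patch."""

    luminance: float
    contrast: float
    edge_density_raw: float
    edge_density: float  # logit-transformed; NaN until the dataset floor is known
    clutter: float
    n_segments: int
    center_xy: tuple[float, float]
    radius_px: int
    clipped: bool


def px_radius_for_degrees(deg: float, px_per_deg: float) -> int:
    """Patch radius in pixels for a visual angle, rounded to the nearest pixel."""
    if not deg > 0:
        raise ValueError("deg must be > 0")
    return int(round(deg * px_per_deg))


def circular_mask(
    center_xy: tuple[float, float], radius_px: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean H x W mask of pixels whose centers lie within radius of center.

    The mask is implicitly clipped to image bounds.  An empty mask (center
    far outside the image) raises :class:`EmptyPatchError`.
    """
    if not radius_px > 0:
        raise ValueError("radius_px must be > 0")
    cx, cy = center_xy
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise ValueError("center coordinates must be finite")
    h, w = shape
    ys = np.arange(h)[:, None]
    xs = np.arange(w)[None, :]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_px ** 2
    if not mask.any():
        raise EmptyPatchError(
            f"patch at ({cx:.1f}, {cy:.1f}) r={radius_px} has no in-bounds pixels"
        )
    return mask


def _masked_values(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = np.asarray(arr)[mask]
    if vals.size == 0:
        raise EmptyPatchError("empty patch mask")
    return vals


def patch_luminance(luminance: np.ndarray, mask: np.ndarray) -> float:
    """Mean normalized luminance under the mask."""
    return float(_masked_values(luminance, mask).mean())


def patch_contrast(
    luminance: np.ndarray, mask: np.ndarray, image_mean_luminance: float
) -> float:
    """RMS contrast: population SD of patch luminance / mean image luminance."""
    if not image_mean_luminance > 0:
        raise ValueError("image mean luminance must be > 0 (degenerate image)")
    vals = _masked_values(luminance, mask)
    return float(vals.std(ddof=0) / image_mean_luminance)


def patch_edge_density(edges: np.ndarray, mask: np.ndarray) -> float:
    """Proportion of edge pixels under the mask, in [0, 1]."""
    return float(_masked_values(edges, mask).mean())


def logit_transform(p: float, p_floor: float) -> float:
    """logit(p) = 0.5 * ln(p / (1 - p)), regularizing 0 to ``p_floor``.

    ``p_floor`` is conventionally the smallest nonzero edge density in the
    analyzed dataset.  Proportions >= 1 are rejected (cannot occur for
    thresholded Sobel maps, guarded anyway).
    """
    if not 0 < p_floor < 1:
        raise ValueError("p_floor must lie in (0, 1)")
    if p < 0 or p >= 1:
        raise ValueError("p must lie in [0, 1)")
    if p == 0:
        p = p_floor
    return 0.5 * np.log(p / (1.0 - p))


def patch_clutter(clutter: np.ndarray, mask: np.ndarray) -> float:
    """Mean clutter under the mask."""
    return float(_masked_values(clutter, mask).mean())


def patch_segment_count(segments: np.ndarray, mask: np.ndarray) -> int:
    """Number of distinct segment labels intersecting the patch."""
    return int(np.unique(_masked_values(segments, mask)).size)


def patch_overlap_fraction(
    center_a: tuple[float, float], center_b: tuple[float, float], radius: float
) -> float:
    """Fractional area overlap of two equal circles (circular-lens form).

    Returns intersection area divided by the area of one circle; 1 for
    coincident centers, 0 for center distance >= 2 radii.
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    d = float(np.hypot(center_a[0] - center_b[0], center_a[1] - center_b[1]))
    if d >= 2 * radius:
        return 0.0
    if d == 0:
        return 1.0
    lens = 2 * radius ** 2 * np.arccos(d / (2 * radius)) - (d / 2) * np.sqrt(
        4 * radius ** 2 - d ** 2
    )
    return float(lens / (np.pi * radius ** 2))


def _circle_offsets(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy ** 2 + dx ** 2 <= radius_px ** 2
    return dy[keep], dx[keep]


def patch_feature_table(
    fixations: pd.DataFrame,
    maps: FeatureMapSet,
    radius_px: int,
    x_col: str = "x",
    y_col: str = "y",
) -> pd.DataFrame:
    """Extract all five patch statistics for every fixation on one scene.

    Vectorized over fixations: feature maps are padded with NaN sentinels so
    border patches clip to in-bounds pixels.  Returns a copy of ``fixations``
    with columns ``luminance``, ``contrast``, ``edge_density_raw``,
    ``clutter``, ``n_segments`` and ``patch_clipped`` appended.  The logit
    transform of edge density is applied later, once the dataset-wide floor
    of nonzero densities is known.
    """
    h, w = maps.luminance.shape
    r = int(radius_px)
    dy, dx = _circle_offsets(r)

    xs = np.rint(fixations[x_col].to_numpy(dtype=float)).astype(int)
    ys = np.rint(fixations[y_col].to_numpy(dtype=float)).astype(int)

    def gather(arr, fill):
        padded = np.full((h + 2 * r, w + 2 * r), fill, dtype=np.float64)
        padded[r : r + h, r : r + w] = arr
        return padded[ys[:, None] + r + dy[None, :], xs[:, None] + r + dx[None, :]]

    lum = gather(maps.luminance, np.nan)
    n_in = np.sum(~np.isnan(lum), axis=1)
    if np.any(n_in == 0):
        bad = np.nonzero(n_in == 0)[0][0]
        raise EmptyPatchError(
            f"fixation at ({xs[bad]}, {ys[bad]}) has no in-bounds patch pixels"
        )
    mean_lum = float(np.asarray(maps.luminance).mean())
    if not mean_lum > 0:
        raise ValueError("image mean luminance must be > 0 (degenerate image)")

    with np.errstate(invalid="ignore"):
        out = fixations.copy()
        out["luminance"] = np.nanmean(lum, axis=1)
        out["contrast"] = np.nanstd(lum, axis=1, ddof=0) / mean_lum
        out["edge_density_raw"] = np.nanmean(gather(maps.edges, np.nan), axis=1)
        out["clutter"] = np.nanmean(gather(maps.clutter, np.nan), axis=1)

    seg = gather(maps.segments, np.nan)
    seg_sorted = np.sort(seg, axis=1)
    first = ~np.isnan(seg_sorted[:, :1])
    distinct = np.diff(seg_sorted, axis=1) > 0
    out["n_segments"] = (
        first.astype(int).ravel() + np.nansum(distinct, axis=1).astype(int)
    )
    out["patch_clipped"] = n_in < dy.size
    return out


def apply_edge_logit(
    table: pd.DataFrame,
    source_cols: tuple[str, ...] = ("edge_density_raw",),
    by: str | None = "task",
    p_floor: float | None = None,
) -> pd.DataFrame:
    """Logit-transform edge-density proportions on a whole analysis table.

    Zero proportions are regularized to the smallest nonzero value in the
    dataset (per ``by`` group, typically per task), or to an explicit
    ``p_floor`` override.  Each ``*_raw`` source column produces a
    transformed column without the suffix (``edge_density_raw`` ->
    ``edge_density``).
    """
    out = table.copy()

    def _transform(group: pd.DataFrame) -> pd.DataFrame:
        for src in source_cols:
            vals = group[src].to_numpy(dtype=float)
            if p_floor is not None:
                floor = p_floor
            else:
                nonzero = vals[vals > 0]
                if nonzero.size == 0:
                    raise ValueError(
                        f"{src}: all proportions are zero; supply p_floor"
                    )
                floor = float(nonzero.min())
            reg = np.where(vals == 0, floor, vals)
            if np.any(reg >= 1):
                raise ValueError(f"{src}: proportions must be < 1")
            tgt = src[: -len("_raw")] if src.endswith("_raw") else src + "_logit"
            group[tgt] = 0.5 * np.log(reg / (1.0 - reg))
        return group

    if by is not None and by in out.columns:
        parts = [_transform(g.copy()) for _, g in out.groupby(by, sort=False)]
        out = pd.concat(parts).sort_index()
    else:
        out = _transform(out)
    return out
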