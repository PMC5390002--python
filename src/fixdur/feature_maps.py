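"""Per-scene feature maps: luminance, edges, clutter, segmentation.

Five maps are computed per scene image; every local patch statistic in the
analysis is derived from them.  All maps share the scene's pixel grid.

* luminance  -- CIE L* of the sRGB image, min-max rescaled to [0, 1]
* edges      -- binary Sobel edge map with an adaptive threshold
* clutter    -- multi-scale feature-congestion clutter, rescaled to [0, 1]
* segments   -- mean-shift-style segmentation into homogeneous regions

The clutter and segmentation maps are in-house implementations of the
feature-congestion and mean-shift families of algorithms; parameters are
fixed, documented defaults (see ``docs/methods.md``) and everything is
deterministic given the configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.color import rgb2lab
from skimage.transform import resize

__all__ = [
    "SceneImage",
    "FeatureMapSet",
    "FeatureMapConfig",
    "luminance_map",
    "edge_map",
    "clutter_map",
    "segment_map",
    "compute_feature_maps",
]


@dataclass(frozen=True)
class SceneImage:
    """A raster scene with a pixels-per-degree calibration.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        sRGB image, channel values in [0, 255].
    px_per_deg : float
        Pixels per degree of visual angle (isotropic; > 0).
    scene_id : str
        Scene identifier.
    """

    pixels: np.ndarray
    px_per_deg: float
    scene_id: str = "scene"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        if not self.px_per_deg > 0:
            raise ValueError("px_per_deg must be > 0")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def center_xy(self) -> tuple[float, float]:
        """Image center in (x, y) pixel coordinates (0-based pixel centers)."""
        h, w = self.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass
class FeatureMapSet:
    """Aligned per-scene feature maps (all H x W)."""

    luminance: np.ndarray  # real, [0, 1]
    edges: np.ndarray  # binary {0, 1}
    clutter: np.ndarray  # real, [0, 1]
    segments: np.ndarray  # integer labels 1..K
    n_segments_total: int
    constant_luminance: bool = False

    def __post_init__(self):
        shapes = {m.shape for m in (self.luminance, self.edges, self.clutter, self.segments)}
        if len(shapes) != 1:
            raise ValueError("all feature maps must share the same shape")


@dataclass
class FeatureMapConfig:
    """Tunable parameters of the feature-map stage.

    sobel_threshold_factor
        Adaptive edge threshold = factor x mean gradient magnitude.
    pyramid_levels
        Number of Gaussian-pyramid levels pooled in the clutter map.
    clutter_weights
        (color, contrast, orientation) mixing weights.
    ms_spatial_bandwidth / ms_range_bandwidth
        Mean-shift window radius in pixels / color bandwidth in CIELab units.
    ms_min_region
        Minimum surviving segment size in pixels; smaller regions are fused
        into their most similar neighbor.
    """

    sobel_threshold_factor: float = 4.0
    pyramid_levels: int = 3
    clutter_weights: tuple[float, float, float] = (0.24, 0.06, 0.70)
    clutter_sigma: float = 3.0
    ms_spatial_bandwidth: int = 7
    ms_range_bandwidth: float = 6.5
    ms_min_region: int = 20
    ms_max_iter: int = 8
    extra: dict = field(default_factory=dict)


def _lab(image: SceneImage) -> np.ndarray:
    """sRGB (IEC 61966-2-1 assumptions) -> CIE L*a*b*."""
    return rgb2lab(image.pixels.astype(np.float64) / 255.0)


def _minmax01(arr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Linear min-max rescale to [0, 1]; (numerically) constant arrays map
    to zeros rather than amplifying float noise."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 1e-9 * max(1.0, abs(hi)):
        return np.zeros_like(arr, dtype=np.float64), True
    return (arr - lo) / (hi - lo), False


def luminance_map(image: SceneImage) -> np.ndarray:
    """CIE L* channel of the image, min-max rescaled to [0, 1].

    A constant image has no luminance range; the map is all zeros and a
    ``UserWarning`` is emitted rather than producing NaNs.
    """
    lum, degenerate = _minmax01(_lab(image)[..., 0])
    if degenerate:
        warnings.warn(
            f"scene {image.scene_id!r}: constant image, luminance map set to 0",
            UserWarning,
            stacklevel=2,
        )
    return lum


def edge_map(luminance: np.ndarray, threshold_factor: float = 4.0) -> np.ndarray:
    """Binary Sobel edge map of a [0, 1] luminance map.

    Gradient magnitude is computed with 3x3 horizontal and vertical Sobel
    kernels (reflect border handling) and binarized at an adaptive threshold
    of ``threshold_factor`` times the mean gradient magnitude.  A constant
    map yields an all-zero edge map.
    """
    lum = np.asarray(luminance, dtype=np.float64)
    gx = ndimage.sobel(lum, axis=1, mode="reflect")
    gy = ndimage.sobel(lum, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    thr = threshold_factor * mag.mean()
    if thr <= 0:
        return np.zeros_like(lum, dtype=np.uint8)
    return (mag > thr).astype(np.uint8)


def _local_std(arr: np.ndarray, sigma: float) -> np.ndarray:
    m = ndimage.gaussian_filter(arr, sigma, mode="reflect")
    m2 = ndimage.gaussian_filter(arr * arr, sigma, mode="reflect")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def _level_clutter(lab: np.ndarray, cfg: FeatureMapConfig) -> np.ndarray:
    """Color, contrast and orientation clutter of one pyramid level."""
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    s = cfg.clutter_sigma

    # color: volume of the local a*,b* covariance ellipse
    ma = ndimage.gaussian_filter(a, s, mode="reflect")
    mb = ndimage.gaussian_filter(b, s, mode="reflect")
    va = ndimage.gaussian_filter(a * a, s, mode="reflect") - ma * ma
    vb = ndimage.gaussian_filter(b * b, s, mode="reflect") - mb * mb
    cab = ndimage.gaussian_filter(a * b, s, mode="reflect") - ma * mb
    det = np.clip(va * vb - cab * cab, 0.0, None)
    color = np.sqrt(np.sqrt(det))

    # contrast: local std of a center-surround (DoG) luminance response
    dog = ndimage.gaussian_filter(L, s / 3.0, mode="reflect") - ndimage.gaussian_filter(
        L, s, mode="reflect"
    )
    contrast = _local_std(dog, s)

    # orientation: mean local std of oriented-derivative energy (4 orientations)
    dx = ndimage.gaussian_filter(L, s / 3.0, order=(0, 1), mode="reflect")
    dy = ndimage.gaussian_filter(L, s / 3.0, order=(1, 0), mode="reflect")
    orient = np.zeros_like(L)
    for theta in (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4):
        energy = (np.cos(theta) * dx + np.sin(theta) * dy) ** 2
        orient += _local_std(energy, s)
    orient /= 4.0

    w_color, w_contrast, w_orient = cfg.clutter_weights
    return w_color * color + w_contrast * contrast + w_orient * orient


def clutter_map(image: SceneImage, config: FeatureMapConfig | None = None) -> np.ndarray:
    """Multi-scale feature-congestion visual clutter, rescaled to [0, 1].

    Local variability of color (a*,b* covariance volume), center-surround
    luminance-contrast energy, and oriented-derivative energy is pooled over
    a Gaussian pyramid and combined as a fixed weighted sum.  A constant
    image has zero feature variability and maps to all zeros.
    """
    cfg = config or FeatureMapConfig()
    lab = _lab(image)
    h, w = lab.shape[:2]
    pooled = np.zeros((h, w), dtype=np.float64)
    level = lab
    n_levels = 0
    for _ in range(cfg.pyramid_levels):
        cl = _level_clutter(level, cfg)
        pooled += resize(cl, (h, w), order=1, mode="reflect", anti_aliasing=False)
        n_levels += 1
        if min(level.shape[:2]) // 2 < 8:
            break
        level = np.stack(
            [
                ndimage.zoom(
                    ndimage.gaussian_filter(level[..., c], 1.0, mode="reflect"),
                    0.5, order=1, mode="reflect", grid_mode=True,
                )
                for c in range(3)
            ],
            axis=-1,
        )
    pooled /= n_levels
    out, _ = _minmax01(pooled)
    return out


def _mode_filter(lab: np.ndarray, cfg: FeatureMapConfig) -> np.ndarray:
    """Iterated local-mode filtering in the joint spatial-CIELab domain.

    Each pixel's color is repeatedly replaced by the mean color of pixels
    within the spatial window whose colors lie within the range bandwidth;
    a fixed-point of this iteration approximates the mean-shift mode map.
    """
    r = cfg.ms_spatial_bandwidth
    hr2 = cfg.ms_range_bandwidth ** 2
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]
    f = lab.copy()
    h, w = f.shape[:2]
    for _ in range(cfg.ms_max_iter):
        padded = np.pad(f, ((r, r), (r, r), (0, 0)), mode="reflect")
        acc = np.zeros_like(f)
        cnt = np.zeros((h, w), dtype=np.float64)
        for dy, dx in offsets:
            nb = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            d2 = ((nb - f) ** 2).sum(axis=-1)
            keep = d2 <= hr2
            acc += nb * keep[..., None]
            cnt += keep
        new = acc / cnt[..., None]
        shift = np.abs(new - f).max()
        f = new
        if shift < 0.05:
            break
    return f


def _label_regions(filtered: np.ndarray, hr: float) -> np.ndarray:
    """Connected components where 4-neighbors lie within the range bandwidth."""
    h, w = filtered.shape[:2]
    idx = np.arange(h * w).reshape(h, w)
    rows, cols = [], []
    # vertical and horizontal adjacency
    for (sl_a, sl_b) in (
        ((slice(0, -1), slice(None)), (slice(1, None), slice(None))),
        ((slice(None), slice(0, -1)), (slice(None), slice(1, None))),
    ):
        d2 = ((filtered[sl_a] - filtered[sl_b]) ** 2).sum(axis=-1)
        link = d2 <= hr * hr
        rows.append(idx[sl_a][link])
        cols.append(idx[sl_b][link])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    graph = coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(h * w, h * w)
    )
    _, labels = connected_components(graph, directed=False)
    return labels.reshape(h, w)


def _fuse_small_regions(
    labels: np.ndarray, filtered: np.ndarray, min_size: int, max_passes: int = 100
) -> np.ndarray:
    """Merge regions smaller than min_size into their most similar neighbor."""
    h, w = labels.shape
    flat_colors = filtered.reshape(-1, 3)
    lab = labels.copy()
    for _ in range(max_passes):
        flat = lab.ravel()
        n = flat.max() + 1
        sizes = np.bincount(flat, minlength=n)
        present = np.nonzero(sizes)[0]
        small = present[sizes[present] < min_size]
        if small.size == 0 or present.size <= 1:
            break
        sums = np.zeros((n, 3))
        np.add.at(sums, flat, flat_colors)
        means = sums[present] / sizes[present, None]
        mean_of = np.zeros((n, 3))
        mean_of[present] = means
        # region adjacency from 4-neighbor label pairs
        pairs = set()
        a, b = lab[:-1, :].ravel(), lab[1:, :].ravel()
        diff = a != b
        pairs.update(zip(a[diff].tolist(), b[diff].tolist()))
        a, b = lab[:, :-1].ravel(), lab[:, 1:].ravel()
        diff = a != b
        pairs.update(zip(a[diff].tolist(), b[diff].tolist()))
        adj: dict[int, set[int]] = {}
        for p, q in pairs:
            adj.setdefault(p, set()).add(q)
            adj.setdefault(q, set()).add(p)
        remap = np.arange(n)
        merged_any = False
        small_set = set(small.tolist())
        for s in small:
            neighbors = [q for q in adj.get(int(s), ()) if q not in small_set]
            if not neighbors:
                neighbors = list(adj.get(int(s), ()))
            if not neighbors:
                continue
            dists = [((mean_of[int(s)] - mean_of[q]) ** 2).sum() for q in neighbors]
            remap[s] = neighbors[int(np.argmin(dists))]
            merged_any = True
        if not merged_any:
            break
        # resolve chains created by small->small merges
        for _ in range(32):
            nxt = remap[remap]
            if np.array_equal(nxt, remap):
                break
            remap = nxt
        lab = remap[lab]
    return lab


def segment_map(
    image: SceneImage, config: FeatureMapConfig | None = None
) -> tuple[np.ndarray, int]:
    """Segment the scene into homogeneous regions; labels 1..K partition it.

    Mean-shift-style mode filtering in the joint spatial-CIELab domain,
    followed by connected-component grouping of similar neighbors and
    fusion of regions below the minimum size.  Deterministic given the
    configuration.
    """
    cfg = config or FeatureMapConfig()
    lab = _lab(image)
    filtered = _mode_filter(lab, cfg)
    labels = _label_regions(filtered, cfg.ms_range_bandwidth)
    labels = _fuse_small_regions(labels, filtered, cfg.ms_min_region)
    uniq, relabeled = np.unique(labels, return_inverse=True)
    seg = (relabeled + 1).reshape(labels.shape).astype(np.int32)
    return seg, int(len(uniq))


def compute_feature_maps(
    image: SceneImage, config: FeatureMapConfig | None = None
) -> FeatureMapSet:
    """Compute all five feature maps for one scene."""
    cfg = config or FeatureMapConfig()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lum = luminance_map(image)
        constant = any(issubclass(c.category, UserWarning) for c in caught)
    edges = edge_map(lum, cfg.sobel_threshold_factor)
    clut = clutter_map(image, cfg)
    seg, n_seg = segment_map(image, cfg)
    return FeatureMapSet(
        luminance=lum,
        edges=edges,
        clutter=clut,
        segments=seg,
        n_segments_total=n_seg,
        constant_luminance=constant,
    )
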