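"""Rosette segmentation from a pot crop.

A decision tree inspects cheap global features of the crop (foreground
fraction of an Otsu mask on the excess-green index, mean foreground hue,
mean green excess) and routes the crop to one of three segmenters: K-means
pixel clustering, hue-histogram analysis, or a shape-assisted hue pipeline.
The chosen method runs several times under randomly perturbed gamma, the
runs are combined by pixel-wise majority vote, and over-segmented regions
(interior holes, narrow notches) are repaired by thresholding a
kernel-smoothed foreground-probability field.  All randomness flows from an
explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage import color as skcolor
from skimage import exposure, morphology
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans


@dataclass
class SegFeatures:
    """Global crop features driving algorithm selection."""

    fg_area_fraction: float
    mean_hue: float          # degrees, [0, 360)
    green_excess_mean: float  # mean of 2G - R - B over the foreground

    def __post_init__(self) -> None:
        if not 0.0 <= self.fg_area_fraction <= 1.0:
            raise ValueError("fg_area_fraction must be in [0, 1]")
        if not 0.0 <= self.mean_hue < 360.0:
            raise ValueError("mean_hue must be in [0, 360)")


@dataclass
class AlgorithmChoice:
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "hue_histogram", "shape_analysis"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class SegmentConfig:
    """Tunable parameters of the segmentation pipeline (with defaults)."""

    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    n_gamma_iters: int = 7
    gamma_range: tuple[float, float] = (0.6, 1.6)
    fg_low: float = 0.01
    fg_high: float = 0.25
    green_excess_cutoff: float = 20.0
    hue_bins: int = 180
    savgol_window: int = 11
    savgol_order: int = 3
    sat_min: float = 0.15
    val_min: float = 0.10
    green_hue_band: tuple[float, float] = (60.0, 180.0)
    spatial_dilation_radius: int = 5
    kmeans_k: int = 3
    repair_sigma: float = 3.0
    min_object_px: int = 30
    apply_clahe: bool = True


def _as_float(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if np.issubdtype(rgb.dtype, np.integer):
        return rgb.astype(float) / 255.0
    return rgb.astype(float)


def green_index(rgb: np.ndarray) -> np.ndarray:
    """Excess-green index ``2G - R - B``, negatives clipped to zero.

    For 8-bit input the result is returned as uint8 (values above 255
    saturate); float input stays float on the same scale.
    """
    rgb = np.asarray(rgb)
    as_int = np.issubdtype(rgb.dtype, np.integer)
    img = rgb.astype(np.int32) if as_int else rgb.astype(float)
    gi = 2 * img[..., 1] - img[..., 0] - img[..., 2]
    if as_int:
        return np.clip(gi, 0, 255).astype(np.uint8)
    return np.clip(gi, 0.0, None)


def enhance_contrast(rgb: np.ndarray, clip_limit: float = 0.01,
                     tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """CLAHE on the HSV value channel; hue and saturation untouched.

    Returns a float RGB image in [0, 1].
    """
    hsv = skcolor.rgb2hsv(_as_float(rgb))
    h, w = hsv.shape[:2]
    kernel = (max(1, h // tile_grid[0]), max(1, w // tile_grid[1]))
    v = hsv[..., 2]
    if np.ptp(v) > 0:
        hsv = hsv.copy()
        hsv[..., 2] = exposure.equalize_adapthist(
            v, kernel_size=kernel, clip_limit=clip_limit)
    return skcolor.hsv2rgb(hsv)


def otsu_binarize(gray: np.ndarray, median_radius: int = 0,
                  gaussian_sigma: float = 0.0, fill_holes: bool = False):
    """Otsu global threshold maximizing the between-class variance.

    The image is histogrammed on its integer levels (float input is scaled
    to 8 bits); ties resolve to the lowest threshold.  The mask keeps pixels
    strictly above the threshold and can optionally be median/Gaussian
    smoothed and hole-filled, as the pipeline does.  A constant image is a
    degenerate input and raises ``ValueError``.
    """
    gray = np.asarray(gray)
    if np.issubdtype(gray.dtype, np.integer):
        levels = gray.astype(int)
    else:
        lo, hi = float(gray.min()), float(gray.max())
        levels = np.zeros(gray.shape, dtype=int) if hi == lo else \
            np.round((gray - lo) / (hi - lo) * 255).astype(int)
    if levels.min() == levels.max():
        raise ValueError("constant image: Otsu threshold undefined")

    hist = np.bincount(levels.ravel(), minlength=levels.max() + 1).astype(float)
    total = hist.sum()
    omega = np.cumsum(hist) / total              # class-0 weight for T = index
    mu = np.cumsum(hist * np.arange(hist.size)) / total
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    threshold = int(np.argmax(sigma_b))          # argmax takes the lowest tie

    mask = levels > threshold
    if median_radius > 0:
        size = 2 * median_radius + 1
        mask = ndimage.median_filter(mask.astype(np.uint8), size=size) > 0
    if gaussian_sigma > 0:
        mask = ndimage.gaussian_filter(mask.astype(float), gaussian_sigma) > 0.5
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if np.issubdtype(gray.dtype, np.integer):
        thr_out: float = float(threshold)
    else:
        thr_out = lo + threshold / 255.0 * (hi - lo)
    return thr_out, mask


def compute_features(rgb: np.ndarray) -> SegFeatures:
    """Otsu-on-green-index foreground statistics used by the decision tree."""
    img = _as_float(rgb)
    gi = green_index(img)
    scale = 255.0
    if np.ptp(gi) < 1e-6:
        return SegFeatures(0.0, 0.0, 0.0)
    _, mask = otsu_binarize(gi)
    if not mask.any():
        return SegFeatures(0.0, 0.0, 0.0)
    hsv = skcolor.rgb2hsv(img)
    mean_hue = float(np.mean(hsv[..., 0][mask]) * 360.0) % 360.0
    return SegFeatures(
        fg_area_fraction=float(mask.mean()),
        mean_hue=mean_hue,
        green_excess_mean=float(np.mean(gi[mask]) * scale),
    )


def select_algorithm(features: SegFeatures,
                     config: SegmentConfig | None = None) -> AlgorithmChoice:
    """Deterministic rule tree mapping crop features to a segmenter.

    Tiny or absent foreground needs the sensitive hue-histogram method;
    a large foreground with weak green excess indicates a cluttered
    background best handled by K-means; everything else goes to the
    shape-assisted hue pipeline.
    """
    config = config or SegmentConfig()
    if features.fg_area_fraction < config.fg_low:
        return AlgorithmChoice("hue_histogram")
    if (features.fg_area_fraction > config.fg_high
            and features.green_excess_mean < config.green_excess_cutoff):
        return AlgorithmChoice("kmeans")
    return AlgorithmChoice("shape_analysis")


def kmeans_background_removal(rgb: np.ndarray, k: int = 3,
                              seed: int = 0) -> np.ndarray:
    """Cluster pixels on (hue, saturation, green index); keep the greenest.

    Clusters whose mean green excess reaches 90 % of the top cluster's are
    retained together with it.  Initialization is seeded, so the mask is
    deterministic.  If the crop has fewer distinct colors than ``k``, the
    cluster count is reduced with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    img = _as_float(rgb)
    hsv = skcolor.rgb2hsv(img)
    gi = green_index(img)
    feats = np.stack([hsv[..., 0], hsv[..., 1], gi], axis=-1).reshape(-1, 3)
    n_unique = np.unique(feats, axis=0).shape[0]
    if n_unique < k:
        warnings.warn(f"only {n_unique} distinct colors; reducing k from {k}")
        k = max(2, n_unique)
        if n_unique < 2:
            # single-color crop: everything or nothing
            return np.full(img.shape[:2], bool(gi.mean() > 0.05))
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(feats)
    labels = km.labels_.reshape(img.shape[:2])
    ge = np.array([gi.reshape(-1)[km.labels_ == i].mean() for i in range(k)])
    top = ge.max()
    keep = np.flatnonzero(ge >= 0.9 * top) if top > 0 else [int(ge.argmax())]
    return np.isin(labels, keep)


def hue_cluster_mask(rgb: np.ndarray, gamma: float = 1.0,
                     config: SegmentConfig | None = None) -> np.ndarray:
    """Hue-histogram segmentation with a spatial-correlation cleanup.

    The gamma-corrected crop's hue histogram (over adequately saturated,
    bright pixels) is smoothed with a Savitzky-Golay filter; the hue
    cluster containing the dominant green mode is bounded at the valleys
    towards neighbouring modes.  Connected components of the resulting mask
    that are not spatially adjacent (within a dilation radius) to the
    dominant plant component are discarded.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    config = config or SegmentConfig()
    img = np.clip(_as_float(rgb), 0.0, 1.0) ** gamma
    hsv = skcolor.rgb2hsv(img)
    hue = hsv[..., 0] * 360.0
    candidates = (hsv[..., 1] >= config.sat_min) & (hsv[..., 2] >= config.val_min)

    lo_band, hi_band = config.green_hue_band
    in_band = candidates & (hue >= lo_band) & (hue <= hi_band)
    if not in_band.any():
        warnings.warn("no green-hue pixels; returning an empty mask")
        return np.zeros(img.shape[:2], dtype=bool)

    nbins = config.hue_bins
    hist, edges = np.histogram(hue[candidates], bins=nbins, range=(0.0, 360.0))
    window = min(config.savgol_window, nbins if nbins % 2 else nbins - 1)
    smooth = savgol_filter(hist.astype(float), window, config.savgol_order)
    smooth = np.clip(smooth, 0.0, None)

    bin_deg = 360.0 / nbins
    band_bins = (edges[:-1] >= lo_band) & (edges[:-1] < hi_band)
    green_mode = int(np.flatnonzero(band_bins)[np.argmax(smooth[band_bins])])
    floor = 0.02 * smooth[green_mode]

    # one cut per side: all hues on the plant side of the curve's
    # intersection (valley) with the dominant non-green mode are kept;
    # without such a mode the cluster extends to where the curve fades out
    def _bound(direction: int) -> int:
        outside = np.flatnonzero(~band_bins & (smooth > floor))
        outside = outside[(outside - green_mode) * direction > 0]
        if outside.size:
            bg_mode = int(outside[np.argmax(smooth[outside])])
            a, b = sorted((green_mode, bg_mode))
            return a + int(np.argmin(smooth[a:b + 1]))
        span = np.arange(green_mode, nbins if direction > 0 else -1, direction)
        alive = span[smooth[span] > floor]
        return int(alive[-1]) if alive.size else green_mode

    lo, hi = _bound(-1), _bound(+1)
    hue_lo, hue_hi = lo * bin_deg, (hi + 1) * bin_deg

    mask = candidates & (hue >= hue_lo) & (hue < hue_hi)
    return _spatial_correlation_filter(mask, config.spatial_dilation_radius)


def _spatial_correlation_filter(mask: np.ndarray, radius: int) -> np.ndarray:
    """Keep components linked (within a dilation radius) to the largest.

    Components are grouped transitively: labelling the dilated mask merges
    every chain of components whose gaps stay below twice the radius, and
    the group containing the dominant plant component is retained.
    """
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    main = int(np.argmax(sizes)) + 1
    grown = morphology.isotropic_dilation(mask, radius)
    groups, _ = ndimage.label(grown, structure=np.ones((3, 3), dtype=int))
    main_group = groups[labels == main][0]
    return mask & (groups == main_group)


def _shape_filtered_mask(rgb: np.ndarray, gamma: float,
                         config: SegmentConfig) -> np.ndarray:
    """Hue pipeline plus shape screening of the surviving components."""
    mask = hue_cluster_mask(rgb, gamma, config)
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    keep = []
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    biggest = sizes.max()
    for lab in range(1, n + 1):
        size = sizes[lab - 1]
        if size == biggest or size >= config.min_object_px:
            keep.append(lab)
    return np.isin(labels, keep)


def consensus_mask(masks: list[np.ndarray]) -> np.ndarray:
    """Pixel-wise majority vote across masks; ties count as foreground."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError("all masks must share one shape")
    votes = np.sum([m.astype(np.int32) for m in masks], axis=0)
    return votes * 2 >= len(masks)


def repair_oversegmentation(mask: np.ndarray, reference: np.ndarray | None = None,
                            sigma: float = 3.0, max_iter: int = 10) -> np.ndarray:
    """Fill interior holes and narrow notches of the rosette region.

    A foreground-probability field is interpolated by Gaussian-kernel
    smoothing of the mask; pixels whose interpolated probability exceeds
    one half are added (never removed), holes are filled, and the update is
    iterated to a fixed point, which makes the operation monotone and
    idempotent.  When a reference crop is supplied, added notch pixels must
    carry a positive excess-green response there.
    """
    out = np.asarray(mask, dtype=bool).copy()
    allowed = None
    if reference is not None:
        allowed = np.asarray(green_index(_as_float(reference))) > 0.0
    for _ in range(max_iter):
        prob = ndimage.gaussian_filter(out.astype(float), sigma)
        add = (prob > 0.5) & ~out
        if allowed is not None:
            add &= allowed
        new = ndimage.binary_fill_holes(out | add)
        if np.array_equal(new, out):
            break
        out = new
    return out


class RosetteSegmenter(BaseEstimator, TransformerMixin):
    """Full segmentation pipeline as a stateless sklearn-style transformer.

    ``transform`` maps a list of RGB pot crops to boolean rosette masks.
    The per-image log of chosen algorithm, gamma values and features is
    kept in ``last_logs_`` after each call.
    """

    def __init__(self, config: SegmentConfig | None = None, seed: int = 0):
        self.config = config
        self.seed = seed

    def fit(self, X=None, y=None):
        return self

    def segment(self, rgb: np.ndarray, seed: int | None = None):
        cfg = self.config or SegmentConfig()
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        img = enhance_contrast(rgb, cfg.clahe_clip_limit, cfg.clahe_tile_grid) \
            if cfg.apply_clahe else _as_float(rgb)
        feats = compute_features(img)
        choice = select_algorithm(feats, cfg)
        gammas = rng.uniform(*cfg.gamma_range, cfg.n_gamma_iters)
        masks = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, gamma in enumerate(gammas):
                if choice.method == "kmeans":
                    m = kmeans_background_removal(
                        np.clip(img, 0, 1) ** gamma, k=cfg.kmeans_k,
                        seed=int((seed + i) % (2 ** 31)))
                elif choice.method == "hue_histogram":
                    m = hue_cluster_mask(img, float(gamma), cfg)
                else:
                    m = _shape_filtered_mask(img, float(gamma), cfg)
                masks.append(m)
        mask = consensus_mask(masks)
        mask = repair_oversegmentation(mask, reference=img, sigma=cfg.repair_sigma)
        mask = ndimage.median_filter(mask.astype(np.uint8), size=3) > 0
        mask = ndimage.binary_fill_holes(mask)
        if cfg.min_object_px > 0:
            mask = morphology.remove_small_objects(
                mask, max_size=cfg.min_object_px - 1)
        log = {"method": choice.method, "gammas": [float(g) for g in gammas],
               "features": {"fg_area_fraction": feats.fg_area_fraction,
                            "mean_hue": feats.mean_hue,
                            "green_excess_mean": feats.green_excess_mean}}
        return mask, log

    def transform(self, X: list[np.ndarray]) -> list[np.ndarray]:
        self.last_logs_ = []
        out = []
        for i, rgb in enumerate(X):
            mask, log = self.segment(rgb, seed=int((self.seed + 9973 * i) % (2 ** 31)))
            self.last_logs_.append(log)
            out.append(mask)
        return out


def segment_rosette(rgb: np.ndarray, config: SegmentConfig | None = None,
                    seed: int = 0) -> np.ndarray:
    """Segment one pot crop; thin wrapper over :class:`RosetteSegmenter`."""
    mask, _ = RosetteSegmenter(config=config, seed=seed).segment(rgb)
    return mask
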