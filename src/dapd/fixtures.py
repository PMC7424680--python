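"""Synthetic fixtures: rendered rosette images and plant-population growth series.

Both generators come with exact ground truth so segmentation, leaf counting
and developmental normalization can be scored without external datasets.

Rosette images emulate a top-view Arabidopsis pot crop: green elliptical
leaves placed around a centre at golden-angle phyllotaxis over a plain,
soil-textured or pot-rim background.  Population series emulate a tray of
genetically identical plants whose leaf number follows an early exponential
trend ``a * exp(b * (t - shift))`` with integer-day germination offsets,
imaged many times per day with multiplicative measurement noise, a diurnal
oscillation of apparent area, and randomly missing frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor
from skimage import draw as skdraw

from .series import SUBDAILY_COLUMNS, TraitSeries

GOLDEN_ANGLE_DEG = 137.5

# ---------------------------------------------------------------------------
# rosette images
# ---------------------------------------------------------------------------


@dataclass
class RosetteSpec:
    """Parameters of a synthetic rosette image.

    ``n_occluded`` renders that many of the ``n_leaves`` leaves fully hidden
    beneath a younger leaf of the same orientation, which makes the
    occlusion term of the measured-leaf-count decomposition concrete: a
    counter that sees only visible leaves must undercount by exactly
    ``n_occluded``.
    """

    n_leaves: int = 6
    leaf_length_px: float = 70.0
    leaf_width_px: float = 26.0
    phyllotaxis_angle: float = GOLDEN_ANGLE_DEG
    overlap_fraction: float = 0.0
    background: str = "plain"  # plain | soil | pot-rim
    noise_sd: float = 3.0
    image_size: tuple[int, int] = (256, 256)
    n_occluded: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image_size must be positive")
        if self.background not in ("plain", "soil", "pot-rim"):
            raise ValueError(f"unknown background {self.background!r}")
        if not 0 <= self.n_occluded <= self.n_leaves // 2:
            raise ValueError("n_occluded must be in [0, n_leaves // 2]")


@dataclass
class GroundTruth:
    """Pixel-exact ground truth of a rendered rosette.

    ``leaf_labels`` labels visible leaves 1..L; L equals
    ``true_leaf_number - occluded_leaf_count`` and the union of labels
    equals ``mask`` exactly.
    """

    mask: np.ndarray
    leaf_labels: np.ndarray
    true_leaf_number: int
    occluded_leaf_count: int
    center: tuple[float, float] = (0.0, 0.0)
    leaf_masks: list = field(default_factory=list)

    @property
    def visible_leaf_number(self) -> int:
        return self.true_leaf_number - self.occluded_leaf_count


class SizingError(ValueError):
    """Raised when the requested rosette cannot fit in the image."""


def _leaf_geometry(spec: RosetteSpec, rng: np.random.Generator):
    """Per-leaf (angle, centre distance, semi-major, semi-minor)."""
    n = spec.n_leaves
    ov = spec.overlap_fraction
    lengths, widths, angles, dists = [], [], [], []
    phase = rng.uniform(0.0, 360.0)
    raw_angles = []
    for i in range(n):
        if ov == 0.0:
            raw_angles.append(phase + i * 360.0 / max(n, 1))
        else:
            raw_angles.append(phase + i * spec.phyllotaxis_angle
                              + rng.uniform(-2.5, 2.5))
    if ov > 0.0 and n > 1:
        # petiole repositioning: real rosette leaves spread to avoid full
        # mutual shading, so near-coincident golden-sequence directions are
        # repelled to a minimum angular gap while keeping their order
        raw_angles = _repel_angles(raw_angles, gap_min_deg=min(20.0, 0.8 * 360.0 / n))
    for i in range(n):
        # older leaves (lower index) are the expanded ones at this stage;
        # the youngest emerge small on top of the rosette
        scale = (1.0 - 0.38 * i / max(n - 1, 1)) * rng.uniform(0.92, 1.05)
        length = spec.leaf_length_px * scale
        width = spec.leaf_width_px * scale
        inner = 6.0 + (1.0 - ov) * 18.0
        if ov == 0.0 and n > 1:
            # push leaves out far enough that neighbours cannot touch
            inner = max(inner, (width + 4.0) / (2.0 * np.sin(np.pi / n)) - length / 2.0)
        lengths.append(length)
        widths.append(width)
        angles.append(np.deg2rad(raw_angles[i]))
        dists.append(inner + length / 2.0)
    return angles, dists, lengths, widths


def _repel_angles(angles_deg, gap_min_deg: float):
    """Enforce a minimum circular gap between directions, preserving order."""
    n = len(angles_deg)
    base = np.mod(angles_deg, 360.0)
    order = np.argsort(base)
    sorted_ang = base[np.array(order)] if isinstance(base, np.ndarray) else \
        np.array([base[i] for i in order])
    for _ in range(4):
        gaps = np.diff(np.concatenate([sorted_ang, [sorted_ang[0] + 360.0]]))
        if (gaps >= gap_min_deg - 1e-6).all():
            break
        gaps = np.maximum(gaps, gap_min_deg)
        gaps *= 360.0 / gaps.sum()
        sorted_ang = sorted_ang[0] + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    out = np.empty(n)
    out[np.array(order)] = sorted_ang
    return out.tolist()


def _draw_leaf(center, angle, dist, length, width, shape, petiole=False):
    cy = center[0] - dist * np.sin(angle)
    cx = center[1] + dist * np.cos(angle)
    rr, cc = skdraw.ellipse(cy, cx, width / 2.0, length / 2.0,
                            rotation=angle, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    if petiole:
        # narrow stalk from the rosette apex to the blade base
        base = dist - length / 2.0 + 2.0
        half = 2.0
        ux, uy = np.cos(angle), -np.sin(angle)     # outward unit vector
        px, py = -uy, ux                           # perpendicular
        corners_y = [center[0] + half * py, center[0] - half * py,
                     center[0] + base * uy - half * py, center[0] + base * uy + half * py]
        corners_x = [center[1] + half * px, center[1] - half * px,
                     center[1] + base * ux - half * px, center[1] + base * ux + half * px]
        rr, cc = skdraw.polygon(corners_y, corners_x, shape=shape)
        m[rr, cc] = True
    return m


def _adjacent_overlap(blades, angles) -> float:
    """Mean pairwise overlap fraction among angularly adjacent leaves."""
    order = np.argsort(np.mod(angles, 2 * np.pi))
    vals = []
    n = len(blades)
    for j in range(n):
        a, b = blades[order[j]], blades[order[(j + 1) % n]]
        sa, sb = a.sum(), b.sum()
        if sa and sb:
            vals.append((a & b).sum() / min(sa, sb))
    return float(np.mean(vals)) if vals else 0.0


def generate_rosette_image(spec: RosetteSpec, seed: int = 0):
    """Render a rosette image and its :class:`GroundTruth`.

    Deterministic for a fixed ``(spec, seed)`` pair.  Raises
    :class:`SizingError` if the rosette cannot fit inside the image.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    angles, dists, lengths, widths = _leaf_geometry(spec, rng)
    if spec.n_leaves:
        extent = max(d + ln / 2.0 for d, ln in zip(dists, lengths))
        if extent > min(h, w) / 2.0 - 2.0:
            raise SizingError(
                f"rosette radius {extent:.0f}px exceeds image half-size "
                f"{min(h, w) / 2.0:.0f}px"
            )

    # fully hidden leaves: re-pose the j-th oldest leaf as a shrunk copy of a
    # young host leaf; it is drawn first, so the host covers it completely
    for j in range(spec.n_occluded):
        host = spec.n_leaves - 1 - j
        angles[j] = angles[host]
        dists[j] = dists[host]
        lengths[j] = lengths[host] * 0.55
        widths[j] = widths[host] * 0.55

    shape = (h, w)
    # draw order: index 0 is the oldest leaf, younger leaves go on top;
    # overlapping rosettes get petioles joining the blades at the apex
    # (zero-overlap rosettes stay blades-only so leaves remain disjoint)
    petiole = spec.overlap_fraction > 0

    def _render(pull: float, with_petioles: bool):
        out = []
        for i in range(spec.n_leaves):
            d = max(lengths[i] / 2.0 + 7.0, dists[i] - pull)
            out.append(_draw_leaf(center, angles[i], d, lengths[i],
                                  widths[i], shape, petiole=with_petioles))
        return out

    # the overlap knob widens blades and pulls them toward the apex, both
    # monotone in the target; blade identity must survive (edge overlap,
    # not base fusion), so the achieved mean adjacent overlap saturates
    # below heavy targets -- early-stage rosettes cannot shade much more
    pull = 18.0 * spec.overlap_fraction if petiole else 0.0
    if petiole:
        widths = [wd * (1.0 + 0.6 * spec.overlap_fraction) for wd in widths]
    leaf_masks = _render(pull, petiole)

    if spec.overlap_fraction == 0.0 and spec.n_occluded == 0:
        # contract: disjoint leaves; shrink widths deterministically if the
        # renderer still produced contact
        for _ in range(8):
            union = np.zeros(shape, dtype=bool)
            ok = True
            for i, m in enumerate(leaf_masks):
                if (m & union).any():
                    ok = False
                    break
                union |= m
            if ok:
                break
            widths = [wd * 0.85 for wd in widths]
            leaf_masks = [
                _draw_leaf(center, angles[i], dists[i], lengths[i], widths[i], shape)
                for i in range(spec.n_leaves)
            ]

    n_total = len(leaf_masks)  # == spec.n_leaves (hidden replace shrunk copies)
    mask = np.zeros(shape, dtype=bool)
    stack_labels = np.zeros(shape, dtype=np.int32)
    for i, m in enumerate(leaf_masks):
        mask |= m
        stack_labels[m] = i + 1

    # occlusion per the >= 95 % cover rule
    occluded = []
    for i, m in enumerate(leaf_masks):
        if not m.any():
            occluded.append(i)
            continue
        younger = np.zeros(shape, dtype=bool)
        for j in range(i + 1, n_total):
            younger |= leaf_masks[j]
        cover = (m & younger).sum() / m.sum()
        if cover >= 0.95:
            occluded.append(i)

    # visible labels 1..L; slivers of occluded leaves go to the covering leaf
    visible = [i for i in range(n_total) if i not in occluded]
    labels = np.zeros(shape, dtype=np.int32)
    for new, i in enumerate(visible, start=1):
        labels[stack_labels == i + 1] = new
    sliver = mask & (labels == 0)
    if sliver.any():
        if visible:
            _, (ir, ic) = ndimage.distance_transform_edt(
                labels == 0, return_indices=True)
            labels[sliver] = labels[ir[sliver], ic[sliver]]
        else:
            labels[sliver] = 1
            visible = [occluded.pop(0)]

    rgb = _render_background(spec, rng, shape)
    for i, m in enumerate(leaf_masks):
        if not m.any():
            continue
        npx = int(m.sum())
        # per-leaf base tone with per-pixel variation, as on real leaves
        hue = (rng.uniform(95.0, 125.0) + rng.normal(0.0, 3.0, npx)) / 360.0
        sat = rng.uniform(0.55, 0.80) + rng.normal(0.0, 0.04, npx)
        val = rng.uniform(0.50, 0.75) + rng.normal(0.0, 0.05, npx)
        hsv_px = np.stack([np.clip(hue, 0.2, 0.45), np.clip(sat, 0.3, 1.0),
                           np.clip(val, 0.2, 1.0)], axis=-1)
        rgb[m] = skcolor.hsv2rgb(hsv_px[None])[0] * 255.0
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        mask=mask,
        leaf_labels=labels,
        true_leaf_number=n_total,
        occluded_leaf_count=len(occluded),
        center=center,
        leaf_masks=leaf_masks,
    )
    return rgb, truth


def _render_background(spec: RosetteSpec, rng: np.random.Generator, shape):
    h, w = shape
    if spec.background == "plain":
        base = np.array([140.0, 135.0, 130.0])
        rgb = np.tile(base, (h, w, 1))
    else:
        # low-saturation brown noise
        hue = 25.0 / 360.0
        sat = np.clip(0.35 + ndimage.gaussian_filter(
            rng.normal(0, 0.35, (h, w)), 2.0), 0.05, 0.6)
        val = np.clip(0.35 + ndimage.gaussian_filter(
            rng.normal(0, 0.35, (h, w)), 2.0), 0.08, 0.6)
        hsv = np.stack([np.full((h, w), hue), sat, val], axis=-1)
        rgb = skcolor.hsv2rgb(hsv) * 255.0
        if spec.background == "pot-rim":
            yy, xx = np.mgrid[0:h, 0:w]
            r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
            rim = (r > 0.44 * min(h, w)) & (r <= 0.49 * min(h, w))
            rgb[rim] = np.array([70.0, 60.0, 58.0])
    return rgb.astype(float)


# ---------------------------------------------------------------------------
# population growth series
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Conditions for a synthetic plant population.

    Defaults describe a tray of 50 Col-0-like plants imaged every 15 minutes
    of a 12-hour day from DAS 12 to 32.  The leaf trend coefficients give
    roughly 2 leaves at day 12 and 12 leaves at day 30; projected area grows
    at 2.4x the leaf rate from ``area_scale`` mm^2 at the timeline origin.
    ``shift_dist`` accepts ``("uniform", lo, hi)`` for iid integer offsets,
    ``("balanced", lo, hi)`` for a shuffled equal-representation design, or
    ``("constant", v)``.
    """

    n_plants: int = 50
    timeline: tuple[int, int] = (12, 32)
    a_dist: tuple[float, float] = (0.9, 0.05)
    b_dist: tuple[float, float] = (0.085, 0.002)
    shift_dist: tuple = ("uniform", -3, 3)
    leaf_noise_sd: float = 0.0       # additive counts per frame
    leaf_noise_cv: float = 0.05      # multiplicative per frame
    area_noise_cv: float = 0.05
    diurnal_amplitude: float = 0.08
    missing_rate: float = 0.15
    frames_per_day: int = 48
    day_start_minute: int = 480      # 08:00
    day_length_minutes: int = 720    # 12 h of light
    area_scale: float = 1.5          # mm^2 at t = 0
    area_rate_ratio: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.timeline[1] - self.timeline[0] + 1 < 3:
            raise ValueError("timeline must span at least 3 days")
        for sd in (self.a_dist[1], self.b_dist[1], self.leaf_noise_sd,
                   self.leaf_noise_cv, self.area_noise_cv):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.frames_per_day < 1:
            raise ValueError("frames_per_day must be >= 1")


def _draw_shifts(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.shift_dist[0]
    if kind == "constant":
        return np.full(spec.n_plants, int(spec.shift_dist[1]))
    lo, hi = int(spec.shift_dist[1]), int(spec.shift_dist[2])
    if kind == "uniform":
        return rng.integers(lo, hi + 1, spec.n_plants)
    if kind == "balanced":
        vals = np.resize(np.arange(lo, hi + 1), spec.n_plants)
        return rng.permutation(vals)
    raise ValueError(f"unknown shift distribution {kind!r}")


def generate_population(spec: PopulationSpec):
    """Simulate a population; returns ``(series_list, true_shifts)``.

    Plant *i*'s noise-free leaf count on day *t* is
    ``round(a_i * exp(b_i * (t - shift_i)))``; its area follows the matching
    exponential with a within-day sinusoidal oscillation.  Measurement noise
    and missing frames are applied per frame; the daily series is the median
    (leaf) / mean (area) of the surviving frames of each day.
    """
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.timeline
    das = np.arange(t0, t1 + 1)
    shifts = _draw_shifts(spec, rng)
    a = np.clip(rng.normal(*spec.a_dist, spec.n_plants), 1e-3, None)
    b = np.clip(rng.normal(*spec.b_dist, spec.n_plants), 1e-4, None)
    c = spec.area_scale * (a / spec.a_dist[0])
    d = spec.area_rate_ratio * b

    tod = (spec.day_start_minute
           + np.arange(spec.frames_per_day) * spec.day_length_minutes
           / spec.frames_per_day).astype(int)
    # oscillation peaks mid-day, zero at the edges of the light period
    diurnal = spec.diurnal_amplitude * np.sin(
        np.pi * (tod - spec.day_start_minute) / spec.day_length_minutes)

    out = []
    for i in range(spec.n_plants):
        leaf_true = a[i] * np.exp(b[i] * (das - shifts[i]))
        area_true = c[i] * np.exp(d[i] * (das - shifts[i]))
        nf = spec.frames_per_day
        leaf_fr = leaf_true[:, None] * (
            1.0 + rng.normal(0.0, spec.leaf_noise_cv, (das.size, nf)))
        if spec.leaf_noise_sd > 0:
            leaf_fr = leaf_fr + rng.normal(0.0, spec.leaf_noise_sd,
                                           (das.size, nf))
        leaf_fr = np.round(np.clip(leaf_fr, 0.0, None))
        area_fr = (area_true[:, None] * (1.0 + diurnal)[None, :]
                   * (1.0 + rng.normal(0.0, spec.area_noise_cv,
                                       (das.size, nf))))
        area_fr = np.clip(area_fr, 0.0, None)
        keep = rng.random((das.size, nf)) >= spec.missing_rate

        frames = pd.DataFrame({
            "das": np.repeat(das, nf),
            "time_of_day": np.tile(tod, das.size),
            "leaf_count": leaf_fr.ravel(),
            "area": area_fr.ravel(),
        })[keep.ravel()].reset_index(drop=True)

        series = daily_series_from_frames(frames, plant_id=f"plant{i:03d}",
                                          timeline=(t0, t1))
        series.flags["true_shift"] = int(shifts[i])
        out.append(series)
    return out, shifts.astype(int)


def daily_series_from_frames(frames: pd.DataFrame, plant_id: str,
                             timeline: tuple[int, int] | None = None) -> TraitSeries:
    """Summarise sub-daily frames into a daily :class:`TraitSeries`.

    Daily leaf count is the median of the day's frames (robust to occasional
    miscounts); daily area is the mean.  Days without frames are flagged
    missing (NaN), never zero.
    """
    frames = frames[SUBDAILY_COLUMNS]
    if timeline is None:
        if frames.empty:
            raise ValueError("cannot infer a timeline from an empty frame table")
        timeline = (int(frames["das"].min()), int(frames["das"].max()))
    das = np.arange(timeline[0], timeline[1] + 1)
    grouped = frames.groupby("das")
    leaf_med = grouped["leaf_count"].median()
    area_mean = grouped["area"].mean()
    leaf = np.array([leaf_med.get(day, np.nan) for day in das])
    area = np.array([area_mean.get(day, np.nan) for day in das])
    return TraitSeries(plant_id=plant_id, das=das, leaf=leaf, area=area,
                       subdaily=frames.reset_index(drop=True))


def inject_missing(series: TraitSeries, rate: float, seed: int = 0) -> TraitSeries:
    """Blank out a seeded pseudo-random subset of days at the given rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = series.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    drop = rng.random(out.das.size) < rate
    out.leaf[drop] = np.nan
    out.area[drop] = np.nan
    if out.subdaily is not None and drop.any():
        dropped_days = set(out.das[drop].tolist())
        out.subdaily = out.subdaily[~out.subdaily["das"].isin(dropped_days)]
        out.subdaily = out.subdaily.reset_index(drop=True)
    out.flags["injected_missing"] = int(drop.sum())
    return out


def default_rosette_suite(seed: int = 0, n_images: int = 20,
                          overlap_fraction: float = 0.2):
    """The canonical seeded evaluation suite of rosette images.

    Twenty images spanning 2-12 leaves on alternating plain and soil
    backgrounds at moderate overlap.  Returns a list of
    ``(spec, image, ground_truth)`` triples.
    """
    out = []
    for i in range(n_images):
        spec = RosetteSpec(
            n_leaves=2 + i % 11,
            overlap_fraction=overlap_fraction,
            background="plain" if i % 2 == 0 else "soil",
        )
        rgb, truth = generate_rosette_image(spec, seed=seed + i)
        out.append((spec, rgb, truth))
    return out
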