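"""Developmental normalization of plant trait time series.

The measured leaf count of a plant decomposes into the real leaf number,
an occlusion deficit and measurement error.  Its early-stage trend is
modelled as an exponential ``leaf_trend(t) = a * exp(b * t)``; the
population reference is the arithmetic mean of the per-plant trends.  Each
plant is then aligned to the reference by the integer-day delay ``s`` that
minimizes the mean squared deviation (MSD) between its shifted daily leaf
counts and the mean trend, and its area series receives an extra whole-day
maturity adjustment ``delta_t`` chosen by the same criterion on log area.
Shifting re-indexes days only; measured values are never interpolated or
rescaled, so within-day (diurnal) structure survives normalization.

Because the arithmetic mean of exponentials is biased toward the most
advanced plants (Jensen's inequality), :class:`DevelopmentalNormalizer`
re-estimates the mean trend from the shifted series and re-selects the
shifts for a few refinement passes; with homogeneous coefficients this
removes a systematic fraction-of-a-day offset that would otherwise corrupt
integer recovery near the rounding boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .series import TraitSeries
from .fixtures import daily_series_from_frames


class FitError(ValueError):
    """Raised when a trend cannot be fitted to a series."""


@dataclass
class TrendModel:
    """Exponential leaf trend ``a * exp(b * t)`` fitted on an early window."""

    a: float
    b: float
    fit_window: tuple[int, int]
    rss: float

    def __call__(self, t):
        return self.a * np.exp(self.b * np.asarray(t, dtype=float))


@dataclass
class PopulationTrend:
    """Pointwise mean of per-plant exponential trends on a day grid."""

    n_plants: int
    timeline: np.ndarray
    mean_leaf_trend: np.ndarray
    mean_area_trend: np.ndarray | None = None


@dataclass
class MSDProfile:
    k_values: np.ndarray
    msd_values: np.ndarray
    n_overlap: np.ndarray


@dataclass
class ShiftSolution:
    plant_id: str
    s: int
    delta_t: int
    profile: MSDProfile | None
    min_msd: float
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def daily_summary(frames: pd.DataFrame, plant_id: str = "plant",
                  timeline: tuple[int, int] | None = None) -> TraitSeries:
    """Collapse sub-daily frames to one leaf/area value per day.

    Daily leaf number is the median of the day's daytime measurements and
    daily area their mean; days without measurements are flagged missing.
    """
    return daily_series_from_frames(frames, plant_id=plant_id, timeline=timeline)


def impute_series(series: TraitSeries, method: str = "spline") -> TraitSeries:
    """Fill interior missing days of both traits; observed values unchanged.

    ``method`` is one of ``spline`` (cubic), ``curve_fit`` (exponential fit
    evaluated at the gaps) or ``upsample`` (linear interpolation on the day
    grid).  Values outside the observed range are never extrapolated.
    """
    if method not in ("spline", "curve_fit", "upsample"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = series.copy()
    for attr in ("leaf", "area"):
        vals = getattr(out, attr)
        obs = np.isfinite(vals)
        if obs.all() or not obs.any():
            continue  # nothing to impute, or the trait was never measured
        if obs.sum() < 4:
            raise FitError(
                f"{series.plant_id}: need >= 4 observed points to impute {attr}")
        t_obs = out.das[obs].astype(float)
        interior = ~obs & (out.das > t_obs.min()) & (out.das < t_obs.max())
        if not interior.any():
            continue
        tq = out.das[interior].astype(float)
        if method == "spline":
            filled = CubicSpline(t_obs, vals[obs])(tq)
        elif method == "upsample":
            filled = np.interp(tq, t_obs, vals[obs])
        else:  # curve_fit: exponential via log-linear least squares
            pos = vals[obs] > 0
            if pos.sum() < 4:
                raise FitError(
                    f"{series.plant_id}: curve_fit needs >= 4 positive points")
            slope, intercept = np.polyfit(t_obs[pos], np.log(vals[obs][pos]), 1)
            filled = np.exp(intercept + slope * tq)
        vals[interior] = np.clip(filled, 0.0, None)
        out.flags.setdefault("imputed_days", {})[attr] = out.das[interior].tolist()
    return out


def fit_leaf_trend(series: TraitSeries, window: tuple[int, int] | None = None,
                   leaf_range: tuple[float, float] = (2.0, 12.0)) -> TrendModel:
    """Log-linear least-squares fit of ``a * exp(b * t)`` to the leaf counts.

    The fit uses the early developmental stages: days whose count lies in
    ``leaf_range`` (and inside ``window``, if given).  ``rss`` is reported on
    the original count scale.
    """
    sel = np.isfinite(series.leaf) & (series.leaf >= max(1.0, leaf_range[0])) \
        & (series.leaf <= leaf_range[1])
    if window is not None:
        sel &= (series.das >= window[0]) & (series.das <= window[1])
    if sel.sum() < 3:
        raise FitError(
            f"{series.plant_id}: fewer than 3 usable points in the fit window")
    t = series.das[sel].astype(float)
    y = series.leaf[sel]
    if np.any(y <= 0):
        raise FitError(f"{series.plant_id}: non-positive counts in fit window")
    b, log_a = np.polyfit(t, np.log(y), 1)
    a = float(np.exp(log_a))
    pred = a * np.exp(b * t)
    return TrendModel(a=a, b=float(b),
                      fit_window=(int(t.min()), int(t.max())),
                      rss=float(np.sum((y - pred) ** 2)))


def population_mean_trend(models: list[TrendModel], timeline,
                          area_models: list[TrendModel] | None = None,
                          shifts=None) -> PopulationTrend:
    """Pointwise arithmetic mean of per-plant trends over ``timeline``.

    If ``shifts`` is given, model *i* is evaluated at ``t - shifts[i]``,
    i.e. the trend of the plant's shifted series.
    """
    if not models:
        raise ValueError("need at least one trend model")
    timeline = np.asarray(timeline, dtype=int)
    if shifts is None:
        shifts = np.zeros(len(models))
    leaf = np.mean([m(timeline - s) for m, s in zip(models, shifts)], axis=0)
    area = None
    if area_models is not None:
        area = np.mean([m(timeline - s) for m, s in zip(area_models, shifts)],
                       axis=0)
    return PopulationTrend(n_plants=len(models), timeline=timeline,
                           mean_leaf_trend=leaf, mean_area_trend=area)


def msd_profile(series: TraitSeries, trend: PopulationTrend,
                k_range: tuple[int, int] = (-7, 7), min_overlap: int = 5,
                score: str = "msd") -> MSDProfile:
    """Mean squared deviation between the k-shifted series and the mean trend.

    For each candidate integer delay ``k`` the shifted series value at day
    ``t`` is the measurement at ``t - k``; the deviation is averaged over
    the ``n`` days where both that measurement and the trend exist.  Delays
    with fewer than ``min_overlap`` overlapping days are excluded.  With
    ``score="xcorr"`` the profile holds ``1 - r`` (Pearson) instead, so the
    minimizer still selects the best alignment.
    """
    if score not in ("msd", "xcorr"):
        raise ValueError(f"unknown score {score!r}")
    t_grid = trend.timeline
    ks, msds, ns = [], [], []
    for k in range(int(k_range[0]), int(k_range[1]) + 1):
        days, s_vals, t_vals = [], [], []
        for j, t in enumerate(t_grid):
            v = series.leaf_at(int(t) - k)
            if np.isfinite(v):
                days.append(t)
                s_vals.append(v)
                t_vals.append(trend.mean_leaf_trend[j])
        if len(days) < min_overlap:
            continue
        s_arr = np.asarray(s_vals)
        t_arr = np.asarray(t_vals)
        if score == "msd":
            val = float(np.mean((s_arr - t_arr) ** 2))
        else:
            sd = s_arr.std()
            val = 1.0 if sd == 0 or t_arr.std() == 0 else \
                float(1.0 - np.corrcoef(s_arr, t_arr)[0, 1])
        ks.append(k)
        msds.append(val)
        ns.append(len(days))
    if not ks:
        raise ValueError(
            f"{series.plant_id}: no delay satisfies the minimum overlap "
            f"of {min_overlap} days")
    return MSDProfile(k_values=np.array(ks), msd_values=np.array(msds),
                      n_overlap=np.array(ns))


def select_shift(profile: MSDProfile) -> int:
    """Delay with the lowest MSD; ties break to smallest ``|k|``, then smaller k."""
    order = sorted(range(profile.k_values.size),
                   key=lambda i: (profile.msd_values[i],
                                  abs(int(profile.k_values[i])),
                                  int(profile.k_values[i])))
    return int(profile.k_values[order[0]])


def area_adjustment(series: TraitSeries, trend: PopulationTrend, s: int,
                    delta_range: tuple[int, int] = (-2, 2),
                    min_overlap: int = 5) -> int:
    """Whole-day maturity adjustment of the area series after the leaf shift.

    ``delta_t`` minimizes the MSD between ``log(area(t - s + delta))`` and
    the log of the population mean area trend, with the same tie-break as
    :func:`select_shift`.  If no candidate has enough overlap the adjustment
    defaults to 0 with a warning.
    """
    if trend.mean_area_trend is None:
        raise ValueError("population trend lacks an area component")
    t_grid = trend.timeline
    best = None
    for delta in range(int(delta_range[0]), int(delta_range[1]) + 1):
        vals, ref = [], []
        for j, t in enumerate(t_grid):
            v = series.area_at(int(t) - s + delta)
            if np.isfinite(v) and v > 0 and trend.mean_area_trend[j] > 0:
                vals.append(np.log(v))
                ref.append(np.log(trend.mean_area_trend[j]))
        if len(vals) < min_overlap:
            continue
        msd = float(np.mean((np.asarray(vals) - np.asarray(ref)) ** 2))
        key = (msd, abs(delta), delta)
        if best is None or key < best:
            best = key
    if best is None:
        warnings.warn(f"{series.plant_id}: insufficient overlap for the area "
                      "adjustment; using delta_t = 0")
        return 0
    return int(best[2])


def apply_shift(series: TraitSeries, s: int, delta_t: int = 0,
                reference_timeline=None) -> TraitSeries:
    """Re-index the series by whole days; values are never altered.

    The normalized leaf value at day ``t`` is the measurement at ``t - s``;
    the normalized area value is the measurement at ``t - s + delta_t``.
    Days falling outside the reference timeline are dropped.  Sub-daily rows
    follow the area rule, preserving the diurnal oscillation untouched.
    """
    if reference_timeline is None:
        reference_timeline = series.das
    ref = np.asarray(reference_timeline, dtype=int)
    leaf = np.array([series.leaf_at(int(t) - s) for t in ref])
    area = np.array([series.area_at(int(t) - s + delta_t) for t in ref])
    subdaily = None
    if series.subdaily is not None:
        subdaily = series.subdaily.copy()
        subdaily["das"] = subdaily["das"] + s - delta_t
        subdaily = subdaily[subdaily["das"].isin(ref)].reset_index(drop=True)
    out = TraitSeries(plant_id=series.plant_id, das=ref, leaf=leaf, area=area,
                      subdaily=subdaily, flags=dict(series.flags))
    out.flags.update({"shift_s": int(s), "shift_delta_t": int(delta_t)})
    return out


# ---------------------------------------------------------------------------
# population-level estimator
# ---------------------------------------------------------------------------


class DevelopmentalNormalizer(BaseEstimator, TransformerMixin):
    """Align a population of trait series by developmental stage.

    ``fit`` learns per-plant exponential leaf and area trends, the
    population mean trend, and each plant's integer shift ``s`` and area
    adjustment ``delta_t``; ``transform`` re-indexes the series accordingly.
    Plants whose trend cannot be fitted pass through unshifted and flagged.

    Parameters
    ----------
    k_range, min_overlap : MSD search window (days) and minimum overlap.
    delta_range : search window for the area maturity adjustment.
    leaf_range : leaf-count band defining the early-stage fit window.
    n_refine : refinement passes of the mean trend / shift estimates.
    impute_method : how interior gaps are filled for estimation only.
    score : ``"msd"`` (primary) or ``"xcorr"``.
    """

    def __init__(self, k_range=(-7, 7), delta_range=(-2, 2),
                 leaf_range=(2.0, 12.0), min_overlap=5, n_refine=3,
                 impute_method="spline", score="msd"):
        self.k_range = k_range
        self.delta_range = delta_range
        self.leaf_range = leaf_range
        self.min_overlap = min_overlap
        self.n_refine = n_refine
        self.impute_method = impute_method
        self.score = score

    # -- internals ---------------------------------------------------------

    def _fit_area_trend(self, series: TraitSeries) -> TrendModel | None:
        sel = np.isfinite(series.area) & (series.area > 0)
        if sel.sum() < 3:
            return None
        t = series.das[sel].astype(float)
        d, log_c = np.polyfit(t, np.log(series.area[sel]), 1)
        c = float(np.exp(log_c))
        pred = c * np.exp(d * t)
        return TrendModel(a=c, b=float(d),
                          fit_window=(int(t.min()), int(t.max())),
                          rss=float(np.sum((series.area[sel] - pred) ** 2)))

    def fit(self, X: list[TraitSeries], y=None):
        if len(X) < 2:
            raise ValueError("need at least 2 plants to normalize")
        imputed = []
        for s in X:
            try:
                imputed.append(impute_series(s, self.impute_method))
            except FitError:
                imputed.append(s.copy())
        self.timeline_ = np.arange(min(int(s.das.min()) for s in X),
                                   max(int(s.das.max()) for s in X) + 1)

        models, area_models, ok = [], [], []
        for s in imputed:
            try:
                models.append(fit_leaf_trend(s, leaf_range=self.leaf_range))
                ok.append(True)
            except FitError:
                models.append(None)
                ok.append(False)
            area_models.append(self._fit_area_trend(s))
        if not any(ok):
            raise FitError("no plant yielded a leaf trend fit")

        fitted = [m for m in models if m is not None]
        fitted_area = [am for m, am in zip(models, area_models)
                       if m is not None and am is not None]

        shifts = np.zeros(len(X), dtype=int)
        profiles: list[MSDProfile | None] = [None] * len(X)
        for _ in range(max(1, int(self.n_refine))):
            trend = population_mean_trend(
                fitted, self.timeline_,
                shifts=[int(s) for s, good in zip(shifts, ok) if good])
            new = shifts.copy()
            for i, s in enumerate(imputed):
                if not ok[i]:
                    continue
                try:
                    profiles[i] = msd_profile(
                        s, trend, k_range=self.k_range,
                        min_overlap=self.min_overlap, score=self.score)
                    new[i] = select_shift(profiles[i])
                except ValueError:
                    ok[i] = False
            if np.array_equal(new, shifts):
                shifts = new
                break
            shifts = new
            fitted = [m for m, good in zip(models, ok) if good]

        area_shifts = [int(s) for s, m, am in zip(shifts, models, area_models)
                       if m is not None and am is not None]
        self.population_trend_ = population_mean_trend(
            fitted, self.timeline_,
            area_models=fitted_area if fitted_area else None,
            shifts=[int(s) for s, good in zip(shifts, ok) if good])
        if fitted_area:
            # area component averaged in the plants' aligned frame as well
            self.population_trend_.mean_area_trend = np.mean(
                [am(self.timeline_ - s)
                 for am, s in zip(fitted_area, area_shifts)], axis=0)

        self.solutions_ = {}
        for i, s in enumerate(X):
            flags = []
            if not ok[i]:
                flags.append("fit_failed")
                sol = ShiftSolution(s.plant_id, 0, 0, profiles[i],
                                    float("nan"), flags)
            else:
                delta = 0
                if self.population_trend_.mean_area_trend is not None:
                    delta = area_adjustment(
                        imputed[i], self.population_trend_, int(shifts[i]),
                        delta_range=self.delta_range,
                        min_overlap=self.min_overlap)
                prof = profiles[i]
                at_s = prof.msd_values[prof.k_values == shifts[i]]
                sol = ShiftSolution(s.plant_id, int(shifts[i]), int(delta),
                                    prof, float(at_s[0]), flags)
            self.solutions_[s.plant_id] = sol
        self.models_ = {s.plant_id: m for s, m in zip(X, models)}
        self.area_models_ = {s.plant_id: m for s, m in zip(X, area_models)}
        return self

    def transform(self, X: list[TraitSeries]) -> list[TraitSeries]:
        out = []
        for s in X:
            sol = self.solutions_.get(s.plant_id)
            if sol is None:
                prof = msd_profile(s, self.population_trend_,
                                   k_range=self.k_range,
                                   min_overlap=self.min_overlap,
                                   score=self.score)
                sol = ShiftSolution(s.plant_id, select_shift(prof), 0, prof,
                                    float(prof.msd_values.min()), ["unseen"])
            shifted = apply_shift(s, sol.s, sol.delta_t,
                                  reference_timeline=self.timeline_)
            if sol.flags:
                shifted.flags["normalization_flags"] = list(sol.flags)
            out.append(shifted)
        return out

    def report(self) -> pd.DataFrame:
        """Audit table: plant_id, s, delta_t, min_msd, flags."""
        rows = [{"plant_id": pid, "s": sol.s, "delta_t": sol.delta_t,
                 "min_msd": sol.min_msd, "flags": ";".join(sol.flags)}
                for pid, sol in self.solutions_.items()]
        return pd.DataFrame(rows)


def normalize_population(dataset: list[TraitSeries], **params):
    """One-call normalization: returns ``(normalized, report, normalizer)``."""
    norm = DevelopmentalNormalizer(**params).fit(dataset)
    return norm.transform(dataset), norm.report(), norm
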