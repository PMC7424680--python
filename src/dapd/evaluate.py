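"""Evaluation harness: segmentation accuracy, dispersion curves, outliers.

Segmentation is scored per mask pair with precision, recall, Jaccard and
Dice on the percent scale; dataset rows aggregate to an unweighted mean row.
Population dispersion is summarised as per-day mean and sample SD of the
projected area, and the raw/normalized SD ratio quantifies how much
developmental normalization tightens the measurements.  Outliers are plants
whose area deviates from the population median by more than a robust-z
threshold for several consecutive days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .series import TraitSeries

MAD_SCALE = 1.4826  # makes the MAD a consistent sigma estimate for normal data


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class SegmentationMetrics:
    """Precision/recall/Jaccard/Dice on the percent scale."""

    precision: float
    recall: float
    jaccard: float
    dice: float
    degenerate: bool = False


@dataclass
class OutlierReport:
    plant_id: str
    flagged: bool
    first_flag_day: int | None
    deviation_score: pd.Series


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion between a predicted and a ground-truth mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def segmentation_metrics(counts: ConfusionCounts) -> SegmentationMetrics:
    """Scores from pixel counts; empty-vs-empty scores 100 across the board."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp + fn == 0:
        return SegmentationMetrics(100.0, 100.0, 100.0, 100.0, degenerate=True)
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    jaccard = 100.0 * tp / (tp + fp + fn)
    dice = 100.0 * 2 * tp / (2 * tp + fp + fn)
    return SegmentationMetrics(precision, recall, jaccard, dice, degenerate)


def aggregate_metrics(per_dataset: list[SegmentationMetrics] | pd.DataFrame,
                      labels=None) -> pd.DataFrame:
    """Per-dataset metric rows plus an unweighted ``Mean`` row, 2 decimals."""
    if isinstance(per_dataset, pd.DataFrame):
        df = per_dataset[["precision", "recall", "jaccard", "dice"]].copy()
    else:
        if not per_dataset:
            raise ValueError("need at least one dataset row")
        df = pd.DataFrame([{"precision": m.precision, "recall": m.recall,
                            "jaccard": m.jaccard, "dice": m.dice}
                           for m in per_dataset])
    if labels is not None:
        df.index = list(labels)
    mean_row = df.mean(axis=0)
    out = pd.concat([df, mean_row.to_frame().T])
    out.index = list(df.index) + ["Mean"]
    return out.round(2)


def dispersion_curves(dataset: list[TraitSeries]) -> pd.DataFrame:
    """Per-day mean and sample SD of area over plants with a value that day.

    Days observed in fewer than 2 plants are omitted.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 plants")
    days = sorted({int(d) for s in dataset for d in s.das})
    rows = []
    for day in days:
        vals = np.array([s.area_at(day) for s in dataset])
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            continue
        rows.append({"day": day, "mean": vals.mean(),
                     "sd": vals.std(ddof=1), "n": vals.size})
    return pd.DataFrame(rows)


def dispersion_ratio(raw_curves: pd.DataFrame, norm_curves: pd.DataFrame,
                     day: int) -> float:
    """SD_raw(day) / SD_normalized(day); infinity if the normalized SD is 0."""
    try:
        sd_raw = float(raw_curves.loc[raw_curves["day"] == day, "sd"].iloc[0])
        sd_norm = float(norm_curves.loc[norm_curves["day"] == day, "sd"].iloc[0])
    except IndexError:
        raise ValueError(f"day {day} not present in both curve tables") from None
    if sd_norm == 0:
        return float("inf")
    return sd_raw / sd_norm


def sd_growth_shape(curves: pd.DataFrame) -> dict:
    """Compare linear vs exponential fits to an SD-over-time curve.

    Returns R^2 of a straight-line fit and of a log-linear (exponential)
    fit, plus a ``shape`` verdict: ``"exponential"`` when the exponential
    model explains the curve better, else ``"linear"``.
    """
    t = curves["day"].to_numpy(dtype=float)
    sd = curves["sd"].to_numpy(dtype=float)
    keep = sd > 0
    t, sd = t[keep], sd[keep]
    if t.size < 4:
        raise ValueError("need at least 4 days of SD values")

    def r2(y, pred):
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    lin = np.polyfit(t, sd, 1)
    r2_linear = r2(sd, np.polyval(lin, t))
    expo = np.polyfit(t, np.log(sd), 1)
    r2_exponential = r2(sd, np.exp(np.polyval(expo, t)))
    return {
        "r2_linear": float(r2_linear),
        "r2_exponential": float(r2_exponential),
        "growth_rate": float(expo[0]),
        "shape": "exponential" if r2_exponential > r2_linear else "linear",
    }


class MADOutlierDetector(BaseEstimator):
    """Flag plants deviating persistently from the population median area.

    Per day, each plant's robust z is its area deviation from the
    population median divided by the scaled MAD (median absolute deviation
    times 1.4826).  A plant is flagged when ``|z| > mad_threshold`` on at
    least ``persist_days`` consecutive days; ``first_flag_day`` is the day
    the persistence condition is first met.  Days whose MAD is zero are
    skipped.
    """

    def __init__(self, mad_threshold: float = 3.5, persist_days: int = 3):
        self.mad_threshold = mad_threshold
        self.persist_days = persist_days

    def fit(self, X: list[TraitSeries], y=None):
        if len(X) < 5:
            raise ValueError("need at least 5 plants for outlier detection")
        days = sorted({int(d) for s in X for d in s.das})
        med, mad = {}, {}
        for day in days:
            vals = np.array([s.area_at(day) for s in X])
            vals = vals[np.isfinite(vals)]
            if vals.size < 3:
                continue
            m = float(np.median(vals))
            dev = float(np.median(np.abs(vals - m)))
            if dev == 0:
                continue
            med[day], mad[day] = m, MAD_SCALE * dev
        self.days_ = sorted(med)
        self.median_ = med
        self.mad_ = mad
        return self

    def predict(self, X: list[TraitSeries]) -> list[OutlierReport]:
        reports = []
        for s in X:
            z = {}
            for day in self.days_:
                v = s.area_at(day)
                if np.isfinite(v):
                    z[day] = (v - self.median_[day]) / self.mad_[day]
            zs = pd.Series(z)
            flagged, first_day = False, None
            run, prev_day = 0, None
            for day in zs.index:
                exceeds = abs(zs[day]) > self.mad_threshold
                contiguous = prev_day is not None and day == prev_day + 1
                run = (run + 1 if contiguous else 1) if exceeds else 0
                if run >= self.persist_days and not flagged:
                    flagged, first_day = True, int(day)
                prev_day = day
            reports.append(OutlierReport(s.plant_id, flagged, first_day, zs))
        return reports


def detect_outliers(dataset: list[TraitSeries], mad_threshold: float = 3.5,
                    persist_days: int = 3) -> list[OutlierReport]:
    """Fit-and-predict convenience wrapper over :class:`MADOutlierDetector`."""
    det = MADOutlierDetector(mad_threshold=mad_threshold,
                             persist_days=persist_days)
    return det.fit(dataset).predict(dataset)
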