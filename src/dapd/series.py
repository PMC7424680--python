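"""Per-plant trait time series.

A :class:`TraitSeries` holds one plant's daily record of measured leaf
count and projected rosette area on a strictly increasing days-after-sowing
(DAS) grid.  Missing days are represented as NaN, never as zero.  The
optional ``subdaily`` table keeps the raw within-day frames (time of day in
minutes, per-frame leaf count and area) so that diurnal structure survives
any whole-day re-indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SUBDAILY_COLUMNS = ["das", "time_of_day", "leaf_count", "area"]


@dataclass
class TraitSeries:
    """Daily leaf-count and rosette-area series for a single plant.

    Parameters
    ----------
    plant_id : str
        Identifier of the plant.
    das : ndarray of int
        Days after sowing, strictly increasing.
    leaf : ndarray of float
        Daily leaf count (median of daytime frames); NaN marks a missing day.
    area : ndarray of float
        Daily projected rosette area (mean of daytime frames); NaN = missing.
    subdaily : DataFrame, optional
        Raw frames with columns ``das, time_of_day, leaf_count, area``.
    flags : dict
        Free-form bookkeeping (e.g. imputation or normalization flags).
    """

    plant_id: str
    das: np.ndarray
    leaf: np.ndarray
    area: np.ndarray
    subdaily: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.das = np.asarray(self.das, dtype=int)
        self.leaf = np.asarray(self.leaf, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.das.ndim != 1:
            raise ValueError("das must be one-dimensional")
        if self.das.size and np.any(np.diff(self.das) <= 0):
            raise ValueError("das must be strictly increasing")
        if self.leaf.shape != self.das.shape or self.area.shape != self.das.shape:
            raise ValueError("leaf and area must match the das grid")
        if np.any(self.leaf[np.isfinite(self.leaf)] < 0):
            raise ValueError("leaf counts must be non-negative")
        if np.any(self.area[np.isfinite(self.area)] < 0):
            raise ValueError("areas must be non-negative")
        if self.subdaily is not None:
            missing = set(SUBDAILY_COLUMNS) - set(self.subdaily.columns)
            if missing:
                raise ValueError(f"subdaily table lacks columns {sorted(missing)}")

    # -- convenience -------------------------------------------------------

    @property
    def observed_leaf(self) -> np.ndarray:
        """Boolean mask of days with an observed leaf count."""
        return np.isfinite(self.leaf)

    @property
    def observed_area(self) -> np.ndarray:
        return np.isfinite(self.area)

    def leaf_at(self, day: int) -> float:
        """Leaf value at a DAS day, NaN if absent from the grid."""
        idx = np.searchsorted(self.das, day)
        if idx < self.das.size and self.das[idx] == day:
            return float(self.leaf[idx])
        return float("nan")

    def area_at(self, day: int) -> float:
        idx = np.searchsorted(self.das, day)
        if idx < self.das.size and self.das[idx] == day:
            return float(self.area[idx])
        return float("nan")

    def copy(self) -> "TraitSeries":
        return replace(
            self,
            das=self.das.copy(),
            leaf=self.leaf.copy(),
            area=self.area.copy(),
            subdaily=None if self.subdaily is None else self.subdaily.copy(),
            flags=dict(self.flags),
        )

    def __len__(self) -> int:
        return self.das.size
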