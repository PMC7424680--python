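"""Readers and writers for the series CSV schema and image artifacts.

The series schema is one row per measurement frame:
``plant_id, das, time_of_day, leaf_count, area`` with integer DAS,
time of day in minutes and missing measurements left as empty cells.
Purely daily series are written with a single noon row per day.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .fixtures import daily_series_from_frames
from .series import SUBDAILY_COLUMNS, TraitSeries

CSV_COLUMNS = ["plant_id", "das", "time_of_day", "leaf_count", "area"]


class SeriesFormatError(ValueError):
    pass


def write_series_csv(path, dataset: list[TraitSeries]) -> None:
    frames = []
    for s in dataset:
        if s.subdaily is not None:
            tab = s.subdaily.copy()
            tab.insert(0, "plant_id", s.plant_id)
        else:
            tab = pd.DataFrame({
                "plant_id": s.plant_id,
                "das": s.das,
                "time_of_day": 720,
                "leaf_count": s.leaf,
                "area": s.area,
            })
        frames.append(tab[CSV_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6g")


def read_series_csv(path) -> list[TraitSeries]:
    """Load a series CSV; empty cells become missing flags, never zeros."""
    df = pd.read_csv(path)
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SeriesFormatError(
            f"{path}: header lacks columns {sorted(missing_cols)}")
    das = pd.to_numeric(df["das"], errors="coerce")
    bad = das.isna() | (das != das.round())
    if bad.any():
        line = int(df.index[bad][0]) + 2  # 1-based, after the header line
        raise SeriesFormatError(f"{path}: non-integer das at line {line}")
    df["das"] = das.astype(int)
    out = []
    for pid, tab in df.groupby("plant_id", sort=True):
        frames = tab.rename(columns={})[CSV_COLUMNS[1:]]
        frames = frames[SUBDAILY_COLUMNS]
        out.append(daily_series_from_frames(frames.reset_index(drop=True),
                                            plant_id=str(pid)))
    return out


def write_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255))).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_rgb_png(path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(path)


def read_rgb_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_labels_png(path, labels: np.ndarray) -> None:
    Image.fromarray(np.asarray(labels, dtype=np.uint16)).save(path)


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
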