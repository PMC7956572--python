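"""Binning CO concentrations into occupational exposure levels and
attaching a level label to every heart beat.

The four levels follow the ACGIH occupational exposure standards for CO
(TLV-TWA 8 h, TLV-STEL 15 min, peak), used as instantaneous bin edges:

    L1: 0 ppm <= CO < 25 ppm
    L2: 25 ppm <= CO < 200 ppm
    L3: 200 ppm <= CO < 400 ppm
    L4: CO >= 400 ppm

Intervals are lower-inclusive / upper-exclusive and partition [0, inf).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .core import LABEL_COLUMNS, CoSeries, HrSeries

logger = logging.getLogger(__name__)

LEVEL_NAMES = ("L1", "L2", "L3", "L4")

#: ppm bin edges between consecutive levels.
LEVEL_EDGES_PPM = np.array([25.0, 200.0, 400.0])


@dataclass(frozen=True)
class ExposureLevel:
    """One CO exposure level: half-open ppm interval [lower, upper)."""

    name: str
    lower_ppm: float
    upper_ppm: float  # inf for the top level

    def __contains__(self, ppm: float) -> bool:
        return self.lower_ppm <= ppm < self.upper_ppm


LEVELS = (
    ExposureLevel("L1", 0.0, 25.0),
    ExposureLevel("L2", 25.0, 200.0),
    ExposureLevel("L3", 200.0, 400.0),
    ExposureLevel("L4", 400.0, np.inf),
)


def bin_exposure_index(co_ppm: Union[float, np.ndarray]) -> Union[int, np.ndarray]:
    """Level index (0..3) for a ppm value or array; negative ppm is an error."""
    arr = np.asarray(co_ppm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("CO concentration cannot be negative")
    idx = np.digitize(arr, LEVEL_EDGES_PPM)
    return int(idx) if np.isscalar(co_ppm) or arr.ndim == 0 else idx


def bin_exposure(co_ppm: float) -> ExposureLevel:
    """The unique exposure level whose interval contains ``co_ppm``."""
    return LEVELS[bin_exposure_index(float(co_ppm))]


def label_hr(hr: HrSeries, co: CoSeries) -> pd.DataFrame:
    """Attach a CO exposure level to every heart beat by time alignment.

    Each CO reading at tick ``t_k`` is taken to describe the interval
    ``[t_k, t_{k+1})`` (last observation carried forward over the sensor
    cadence; the final reading covers one full cadence). Beats outside
    CO coverage are dropped and counted in a log message.

    Returns the labeled feature table (columns :data:`coexp.core.LABEL_COLUMNS`)
    with ``is_replicate`` False everywhere.
    """
    if len(hr) == 0 or len(co) == 0:
        raise ValueError("need non-empty HR and CO series")
    idx = np.searchsorted(co.t, hr.t, side="right") - 1
    covered = (idx >= 0) & (hr.t < co.t[-1] + co.cadence_s)
    if not covered.any():
        raise ValueError("HR and CO series do not overlap in time")
    n_dropped = int((~covered).sum())
    if n_dropped:
        logger.info(
            "label_hr: dropped %d of %d HR samples outside CO coverage",
            n_dropped,
            len(hr),
        )
    level_idx = bin_exposure_index(co.ppm[idx[covered]])
    return pd.DataFrame(
        {
            "t_s": hr.t[covered],
            "hr_bpm": hr.bpm[covered],
            "level": np.take(LEVEL_NAMES, level_idx),
            "subject_id": hr.subject_id,
            "is_replicate": False,
        }
    )[LABEL_COLUMNS]


def tabulate_levels(ds: pd.DataFrame) -> dict:
    """Per-subject x per-level sample counts and exposure durations.

    Durations are count-weighted beat intervals: each beat at rate h
    beats/min occupies 1/h minutes. Returns ``{"counts": DataFrame,
    "duration_min": DataFrame}``, each with subjects as rows, levels as
    columns and a "Total" row/column.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    counts = (
        ds.pivot_table(index="subject_id", columns="level", values="hr_bpm", aggfunc="size", fill_value=0)
        .reindex(columns=list(LEVEL_NAMES), fill_value=0)
        .astype(int)
    )
    dur = (
        ds.assign(beat_min=1.0 / ds["hr_bpm"])
        .pivot_table(index="subject_id", columns="level", values="beat_min", aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(LEVEL_NAMES), fill_value=0.0)
    )
    for table in (counts, dur):
        table.loc["Total"] = table.sum(axis=0)
        table["Total"] = table.sum(axis=1)
    return {"counts": counts, "duration_min": dur}
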