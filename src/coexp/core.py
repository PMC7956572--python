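"""Shared in-memory containers for the heart-rate / CO-exposure pipeline.

The pipeline passes three signal containers between stages:

``EcgRecord``
    A single-lead ECG trace in millivolts at a fixed sampling rate
    (wearable chest ECG, nominally 500 samples/s).
``HrSeries``
    Beat-to-beat heart rate in beats/min, one value per R-R interval,
    stamped at the interval end.
``CoSeries``
    Carbon-monoxide concentration in ppm sampled at a fixed cadence
    (nominally one reading per 60 s from an electrochemical sensor
    capped at 500 ppm).

The labeled feature table (one row per heart beat with its exposure-level
label) is an ordinary :class:`pandas.DataFrame` with the columns in
:data:`LABEL_COLUMNS`; see :mod:`coexp.labeling`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the labeled HR feature table.
LABEL_COLUMNS = ["t_s", "hr_bpm", "level", "subject_id", "is_replicate"]

#: CO sensor ceiling in ppm.
CO_SENSOR_MAX_PPM = 500.0


@dataclass
class EcgRecord:
    """Single-lead ECG samples (mV) at a fixed sampling rate (samples/s)."""

    samples: np.ndarray
    rate: float
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("ECG samples must be a 1-D array")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def replace_samples(self, samples: np.ndarray) -> "EcgRecord":
        """A copy of this record with new samples (rate and id kept)."""
        return EcgRecord(samples=samples, rate=self.rate, subject_id=self.subject_id)


@dataclass
class HrSeries:
    """Per-beat heart rate.

    ``bpm[i]`` is the instantaneous rate of the i-th R-R interval and
    ``t[i]`` the time (s) of that interval's end.
    """

    bpm: np.ndarray
    t: np.ndarray
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.bpm.shape != self.t.shape or self.bpm.ndim != 1:
            raise ValueError("bpm and t must be 1-D arrays of equal length")
        if len(self.bpm) and not np.all(np.isfinite(self.bpm)):
            raise ValueError("heart rate contains non-finite values")
        if len(self.bpm) and not np.all(self.bpm > 0):
            raise ValueError("heart rate must be strictly positive")

    def __len__(self) -> int:
        return len(self.bpm)


@dataclass
class CoSeries:
    """CO concentration (ppm) at a fixed cadence; ``t`` in seconds."""

    t: np.ndarray
    ppm: np.ndarray
    cadence_s: float = 60.0
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.t.shape != self.ppm.shape or self.t.ndim != 1:
            raise ValueError("t and ppm must be 1-D arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("CO timestamps must be strictly increasing")
        if len(self.ppm) and np.any(self.ppm < 0):
            raise ValueError("CO concentration cannot be negative")
        if not self.cadence_s > 0:
            raise ValueError("cadence must be positive")

    def __len__(self) -> int:
        return len(self.t)


def largest_remainder_allocation(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``.

    Floors the exact shares and hands the remaining units to the cells
    with the largest fractional remainders (ties broken by cell order),
    so the result always sums to ``total``.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    exact = weights / weights.sum() * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainders = exact - counts
        # stable: larger remainder first, then original order
        order = np.lexsort((np.arange(len(weights)), -remainders))
        counts[order[:short]] += 1
    return counts


def validate_labeled(ds: pd.DataFrame) -> pd.DataFrame:
    """Check the labeled-HR table schema and basic invariants."""
    missing = [c for c in LABEL_COLUMNS if c not in ds.columns]
    if missing:
        raise ValueError(f"labeled dataset missing columns: {missing}")
    # >= 0 rather than > 0: min-max scaling maps each group minimum to 0
    if len(ds) and not (ds["hr_bpm"] >= 0).all():
        raise ValueError("hr_bpm must be non-negative")
    return ds
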