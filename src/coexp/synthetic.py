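"""Synthetic paired CO / heart-rate / ECG streams.

The real field recordings (wearable chest ECG plus a belt-mounted CO
sensor worn during experimental burns) are not publicly available, so
this module generates data with the statistical structure the analysis
assumes and the downstream stages can be tested against:

* a CO concentration profile at fixed cadence — flat low baseline with
  sharp bursts that decay back down, occupying each exposure level for
  a configurable fraction of time;
* a beat-to-beat heart-rate trajectory whose within-level median is the
  configured per-level median (strictly increasing with level);
* a single-lead ECG built by placing a stereotyped PQRST template at
  R-times spaced ``round(60 * rate / HR_i)`` samples apart — the exact
  inverse of the beat-to-beat HR equation — with optional baseline
  drift and white noise for robustness tests.

All randomness comes from one :class:`numpy.random.Generator` per call,
seeded explicitly, so outputs are bit-identical across runs.
"""

from __future__ import annotations

import zlib
from typing import Optional

import numpy as np

from .config import ScenarioConfig
from .core import CO_SENSOR_MAX_PPM, CoSeries, EcgRecord, HrSeries, largest_remainder_allocation
from .labeling import bin_exposure_index

# ppm interval available to the generator inside each level (upper edges
# pulled in by 1 ppm so jitter cannot cross a bin boundary).
_LEVEL_PPM_BOUNDS = ((0.0, 24.0), (25.0, 199.0), (200.0, 399.0), (400.0, CO_SENSOR_MAX_PPM - 1.0))

# PQRST template as a Gaussian sum: (amplitude mV, center s, width s).
# Only the R timing matters downstream; widths are kept narrow so the
# template argmax stays on the R center to within a sample.
_PQRST_WAVES = (
    (0.12, -0.19, 0.025),  # P
    (-0.10, -0.03, 0.012),  # Q
    (1.00, 0.00, 0.010),  # R
    (-0.22, 0.03, 0.012),  # S
    (0.30, 0.20, 0.040),  # T
)


def _subject_seed(cfg_seed: int, subject: str) -> int:
    """Stable per-subject seed below 2**31."""
    return (int(cfg_seed) * 100003 + zlib.crc32(subject.encode())) % (2**31)


def generate_co_profile(cfg: ScenarioConfig, subject: str = "S0", seed: Optional[int] = None) -> CoSeries:
    """One CO reading per cadence tick for the configured duration.

    Time in each exposure level matches ``cfg.level_shares`` exactly at
    tick granularity (largest-remainder allocation). Elevated-level
    ticks are grouped into burst episodes of roughly
    ``cfg.burst.duration_s`` each, placed at random among the baseline
    ticks; within a burst the concentration starts near the top of the
    episode's highest level and decays exponentially, mimicking a sharp
    CO excursion followed by clearance.
    """
    rng = np.random.default_rng(_subject_seed(cfg.seed, subject) if seed is None else seed)
    n_ticks = int(round(cfg.duration_min * 60.0 / cfg.co_cadence_s))
    if n_ticks < 1:
        raise ValueError("duration shorter than one CO cadence tick")
    counts = largest_remainder_allocation(np.asarray(cfg.level_shares), n_ticks)

    n_elev = int(counts[1:].sum())
    levels_seq = np.zeros(n_ticks, dtype=int)
    if n_elev > 0:
        n_bursts = int(max(1, min(n_elev, round(n_elev * cfg.co_cadence_s / cfg.burst.duration_s))))
        # per-burst tick counts for each elevated level
        per_burst = {
            lvl: largest_remainder_allocation(np.ones(n_bursts), int(counts[lvl]))
            if counts[lvl] > 0
            else np.zeros(n_bursts, dtype=int)
            for lvl in (1, 2, 3)
        }
        # burst b: highest level first, then decay through lower levels
        bursts = [
            np.concatenate([np.full(per_burst[lvl][b], lvl, dtype=int) for lvl in (3, 2, 1)])
            for b in range(n_bursts)
        ]
        bursts = [b for b in bursts if len(b)]
        gaps = rng.multinomial(int(counts[0]), np.full(len(bursts) + 1, 1.0 / (len(bursts) + 1)))
        pieces = []
        for b, burst in enumerate(bursts):
            pieces.append(np.zeros(gaps[b], dtype=int))
            pieces.append(burst)
        pieces.append(np.zeros(gaps[-1], dtype=int))
        levels_seq = np.concatenate(pieces)

    ppm = np.empty(n_ticks)
    base = cfg.burst.baseline_ppm
    peak_cap = min(base + cfg.burst.amplitude_ppm, CO_SENSOR_MAX_PPM - 1.0)
    # fill runs of constant level with a decaying profile inside the bin
    run_starts = np.flatnonzero(np.r_[True, np.diff(levels_seq) != 0])
    run_ends = np.r_[run_starts[1:], n_ticks]
    for s, e in zip(run_starts, run_ends):
        lvl = levels_seq[s]
        m = e - s
        if lvl == 0:
            vals = base + rng.normal(0.0, 1.0, m)
            ppm[s:e] = np.clip(vals, 0.0, _LEVEL_PPM_BOUNDS[0][1])
        else:
            low, high = _LEVEL_PPM_BOUNDS[lvl]
            high = min(high, max(low + 1.0, peak_cap))
            j = np.arange(m)
            vals = low + (high - low) * np.exp(-3.0 * j / max(m - 1, 1))
            vals = vals + rng.normal(0.0, 0.02 * (high - low), m)
            ppm[s:e] = np.clip(vals, low, high)
    t = np.arange(n_ticks) * cfg.co_cadence_s
    return CoSeries(t=t, ppm=np.clip(ppm, 0.0, CO_SENSOR_MAX_PPM), cadence_s=cfg.co_cadence_s, subject_id=subject)


def generate_hr_trajectory(cfg: ScenarioConfig, co: CoSeries, seed: Optional[int] = None) -> HrSeries:
    """Beat-to-beat HR driven by the CO exposure level.

    Every beat whose R-R interval starts inside CO tick k draws
    ``HR ~ Normal(hr_medians[level_k], hr_sd)``, clipped to the
    physiological range [40, 220] beats/min. The beat clock advances by
    60/HR seconds per beat, so a 5 h record at ~110 beats/min yields
    roughly 33,000 beats. A fixed block of draws is consumed per tick,
    making the output independent of how many beats each tick holds.
    """
    if len(co) == 0:
        raise ValueError("CO series is empty")
    rng = np.random.default_rng(_subject_seed(cfg.seed, co.subject_id) if seed is None else seed)
    levels = bin_exposure_index(co.ppm)
    cadence = co.cadence_s
    # enough draws for the fastest physiological rate (220 bpm)
    block = int(np.ceil(cadence * 220.0 / 60.0)) + 2
    bpm_parts = []
    t_parts = []
    t = float(co.t[0])
    for k in range(len(co)):
        tick_end = co.t[0] + (k + 1) * cadence
        draws = rng.normal(cfg.hr_medians[levels[k]], cfg.hr_sd, block)
        hr = np.clip(draws, 40.0, 220.0)
        intervals = 60.0 / hr
        ends = t + np.cumsum(intervals)
        starts = ends - intervals
        take = starts < tick_end
        n_take = int(take.sum())
        if n_take:
            bpm_parts.append(hr[:n_take])
            t_parts.append(ends[:n_take])
            t = float(ends[n_take - 1])
    return HrSeries(
        bpm=np.concatenate(bpm_parts) if bpm_parts else np.empty(0),
        t=np.concatenate(t_parts) if t_parts else np.empty(0),
        subject_id=co.subject_id,
    )


def pqrst_template(rate: float) -> np.ndarray:
    """Stereotyped one-beat waveform (mV) sampled at ``rate``; R at index
    ``int(0.25 * rate)``."""
    t = np.arange(-int(0.25 * rate), int(0.30 * rate) + 1) / rate
    wave = np.zeros_like(t)
    for amp, mu, sigma in _PQRST_WAVES:
        wave += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return wave


def generate_ecg_from_hr(
    hr: HrSeries,
    cfg: ScenarioConfig,
    drift_mv: float = 0.0,
    noise_sd_mv: float = 0.0,
    seed: Optional[int] = None,
) -> EcgRecord:
    """Synthesize a single-lead ECG whose R-R spacings invert the HR.

    Successive R peaks are ``round(60 * rate / HR_i)`` samples apart, so
    running the ECG processing chain on the output recovers the input
    HR (exactly when the spacing is an integer number of samples).
    ``drift_mv`` adds a 0.3 Hz sinusoidal baseline wander and
    ``noise_sd_mv`` additive white noise; both default to off.
    """
    if len(hr) == 0:
        raise ValueError("HR series is empty")
    if np.any(hr.bpm < 40.0) or np.any(hr.bpm > 220.0):
        raise ValueError("HR outside the supported [40, 220] bpm range")
    rate = cfg.ecg_rate
    spacings = np.rint(60.0 * rate / hr.bpm).astype(int)
    r0 = int(round(0.5 * rate))
    r_idx = np.concatenate([[r0], r0 + np.cumsum(spacings)])
    n = int(r_idx[-1] + round(0.5 * rate))
    x = np.zeros(n)
    tpl = pqrst_template(rate)
    r_off = int(0.25 * rate)  # R position inside the template
    for r in r_idx:
        lo = r - r_off
        hi = lo + len(tpl)
        a = max(lo, 0)
        b = min(hi, n)
        x[a:b] += tpl[a - lo : len(tpl) - (hi - b)]
    if drift_mv or noise_sd_mv:
        rng = np.random.default_rng(_subject_seed(cfg.seed, hr.subject_id) if seed is None else seed)
        if drift_mv:
            x += drift_mv * np.sin(2.0 * np.pi * 0.3 * np.arange(n) / rate)
        if noise_sd_mv:
            x += rng.normal(0.0, noise_sd_mv, n)
    return EcgRecord(samples=x, rate=rate, subject_id=hr.subject_id)
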