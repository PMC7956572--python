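"""Configuration objects for the simulation, balancing and classification stages.

All tunables live here so a whole run is reproducible from one config +
one seed. Defaults describe the field-campaign conditions the synthetic
generator emulates: three subjects monitored for ~5 h each at 500 Hz ECG
and 60 s CO cadence, with the exposure-level time shares observed in the
campaign (level 1 dominant, level 3 rare, level 4 never reached).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

_LEVEL_COUNT = 4


@dataclass(frozen=True)
class BurstModel:
    """Shape of CO excursions: flat baseline plus sharp bursts that decay.

    ``baseline_ppm``   ambient CO between bursts (well inside level 1);
    ``amplitude_ppm``  how far above baseline a burst peaks;
    ``duration_s``     nominal length of one burst episode — together with
                       the level shares this sets how many bursts occur.
    """

    baseline_ppm: float = 5.0
    amplitude_ppm: float = 350.0
    duration_s: float = 900.0

    def __post_init__(self) -> None:
        if self.baseline_ppm < 0 or self.amplitude_ppm <= 0 or self.duration_s <= 0:
            raise ValueError("burst-model parameters must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Synthetic-campaign scenario.

    ``level_shares`` is the fraction of monitoring time spent in each CO
    exposure level L1..L4 (defaults follow the observed campaign shares,
    82.49 / 13.97 / 3.54 / 0 %). ``hr_medians`` are the per-level median
    heart rates in beats/min and must be strictly increasing with level
    — the structure the analysis is designed to detect; ``hr_sd`` is the
    within-level beat-to-beat spread.
    """

    n_subjects: int = 3
    duration_min: float = 300.0
    ecg_rate: float = 500.0
    co_cadence_s: float = 60.0
    level_shares: Tuple[float, ...] = (0.8249, 0.1397, 0.0354, 0.0)
    hr_medians: Tuple[float, ...] = (110.0, 120.0, 128.0, 136.0)
    hr_sd: float = 8.0
    burst: BurstModel = field(default_factory=BurstModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if not self.ecg_rate > 0:
            raise ValueError("ecg_rate must be positive")
        if not self.co_cadence_s > 0:
            raise ValueError("co_cadence_s must be positive")
        if len(self.level_shares) != _LEVEL_COUNT:
            raise ValueError("level_shares must have one entry per level L1..L4")
        if any(s < 0 for s in self.level_shares):
            raise ValueError("level shares must be non-negative")
        if abs(sum(self.level_shares) - 1.0) > 1e-9:
            raise ValueError("level shares must sum to 1")
        if len(self.hr_medians) != _LEVEL_COUNT:
            raise ValueError("hr_medians must have one entry per level L1..L4")
        if any(b >= a for a, b in zip(self.hr_medians[1:], self.hr_medians[:-1])):
            raise ValueError("hr_medians must be strictly increasing with level")
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be non-negative")


@dataclass(frozen=True)
class BalanceConfig:
    """Gaussian-replicate oversampling parameters.

    ``noise_sd`` is the replicate jitter on the [0, 1] scaled HR axis;
    ``target_count`` defaults to the majority-class count.
    """

    noise_sd: float = 0.01
    seed: int = 0
    target_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class EnsembleConfig:
    """Bagged-tree ensemble and evaluation protocol."""

    n_trees: int = 100
    method: str = "bagging"  # bagging (faithful) | adaboost | rusboost
    cv_folds: int = 10
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.method not in ("bagging", "adaboost", "rusboost"):
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run.

    ``mode`` controls where oversampling happens relative to the
    train/test split and the CV folds: ``"faithful"`` oversamples the
    whole dataset first (replicates can then land on both sides of a
    split, which inflates hold-out scores); ``"leakage_safe"`` splits
    first and oversamples training data only.

    ``ecg_synthesis=True`` runs the full chain (HR → synthetic ECG →
    filtering → R-peak detection → HR) instead of using the generated
    HR directly; it validates the signal path at ~9 M ECG samples per
    simulated hour.
    """

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    alpha: float = 0.05
    mode: str = "faithful"
    ecg_synthesis: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("faithful", "leakage_safe"):
            raise ValueError(f"unknown mode {self.mode!r}")


def run_config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a nested plain dict (e.g. parsed YAML)."""
    d = dict(d)
    scen = dict(d.pop("scenario", {}))
    burst = scen.pop("burst", None)
    if burst is not None:
        scen["burst"] = BurstModel(**burst)
    if "level_shares" in scen:
        scen["level_shares"] = tuple(scen["level_shares"])
    if "hr_medians" in scen:
        scen["hr_medians"] = tuple(scen["hr_medians"])
    return RunConfig(
        scenario=ScenarioConfig(**scen),
        balance=BalanceConfig(**d.pop("balance", {})),
        ensemble=EnsembleConfig(**d.pop("ensemble", {})),
        **d,
    )


def run_config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)
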