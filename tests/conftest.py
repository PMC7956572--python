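import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coexp.config import ScenarioConfig
from coexp import labeling, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario_small() -> ScenarioConfig:
    """A 30-minute campaign slice used by most unit tests."""
    return ScenarioConfig(duration_min=30.0, seed=7)


@pytest.fixture(scope="session")
def labeled_small(scenario_small) -> pd.DataFrame:
    """Labeled beats for three subjects of the small scenario."""
    parts = []
    for i in range(3):
        subject = f"FF{i + 1}"
        co = synthetic.generate_co_profile(scenario_small, subject)
        hr = synthetic.generate_hr_trajectory(scenario_small, co)
        parts.append(labeling.label_hr(hr, co))
    return pd.concat(parts, ignore_index=True)


def make_labeled(class_counts: dict, scaled: bool = False, seed: int = 0) -> pd.DataFrame:
    """A labeled table with exact per-level row counts.

    HR values are drawn per level from narrow, well-separated uniform
    bands (raw bpm by default, [0, 1] bands when ``scaled``).
    """
    rng = np.random.default_rng(seed)
    bands_raw = {"L1": (100, 115), "L2": (118, 130), "L3": (132, 150), "L4": (150, 160)}
    bands_scaled = {"L1": (0.0, 0.3), "L2": (0.35, 0.6), "L3": (0.65, 1.0), "L4": (0.9, 1.0)}
    bands = bands_scaled if scaled else bands_raw
    parts = []
    t0 = 0.0
    for level, n in class_counts.items():
        lo, hi = bands[level]
        parts.append(
            pd.DataFrame(
                {
                    "t_s": t0 + np.arange(n) * 0.5,
                    "hr_bpm": rng.uniform(lo, hi, n),
                    "level": level,
                    "subject_id": "FF1",
                    "is_replicate": False,
                }
            )
        )
        t0 += n
    return pd.concat(parts, ignore_index=True)
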