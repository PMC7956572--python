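"""coexp: classifying carbon-monoxide exposure levels from heart rate.

A reusable pipeline for occupational-exposure analysis with wearable
single-lead ECG: ECG preprocessing and beat-to-beat heart rate, CO
exposure-level labeling against occupational exposure standards,
class balancing by Gaussian replicates, nonparametric group comparison,
and bagged-tree classification with cross-validated evaluation. A
synthetic-data module generates paired ECG/CO streams so the whole
chain is testable without field recordings.
"""

from .config import BalanceConfig, BurstModel, EnsembleConfig, RunConfig, ScenarioConfig
from .core import CoSeries, EcgRecord, HrSeries
from .pipeline import PipelineError, run_pipeline

__version__ = "0.1.0"

__all__ = [
    "BalanceConfig",
    "BurstModel",
    "CoSeries",
    "EcgRecord",
    "EnsembleConfig",
    "HrSeries",
    "PipelineError",
    "RunConfig",
    "ScenarioConfig",
    "run_pipeline",
    "__version__",
]
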