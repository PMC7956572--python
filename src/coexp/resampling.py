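"""Class balancing by Gaussian-noise replication and [0, 1] scaling.

Heart rate is first min-max scaled (per subject by default, so the
classifier sees inter-subject-comparable values), then every minority
exposure level is topped up to the majority-class count with noisy
copies of its own rows: a source row is drawn uniformly with
replacement and Gaussian noise N(0, noise_sd^2) is added to its scaled
HR, clipped back into [0, 1]. Original rows pass through verbatim with
``is_replicate`` False; replicates are flagged True.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .config import BalanceConfig
from .core import validate_labeled

ScaleParams = Dict[str, Tuple[float, float]]  # group -> (min, max)

_GLOBAL_GROUP = "__all__"


def minmax_scale(ds: pd.DataFrame, per_subject: bool = True) -> Tuple[pd.DataFrame, ScaleParams]:
    """Map ``hr_bpm`` affinely onto [0, 1] within each scaling group.

    Returns the scaled copy and the per-group ``(min, max)`` needed to
    invert the transform. Groups with fewer than two distinct values
    cannot be scaled and raise.
    """
    validate_labeled(ds)
    out = ds.copy()
    params: ScaleParams = {}
    groups = out.groupby("subject_id").groups if per_subject else {_GLOBAL_GROUP: out.index}
    for name, idx in groups.items():
        vals = out.loc[idx, "hr_bpm"].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if lo == hi:
            raise ValueError(f"cannot min-max scale constant group {name!r}")
        out.loc[idx, "hr_bpm"] = (vals - lo) / (hi - lo)
        params[str(name)] = (float(lo), float(hi))
    return out, params


def inverse_scale(ds: pd.DataFrame, params: ScaleParams) -> pd.DataFrame:
    """Undo :func:`minmax_scale` given its returned parameters."""
    out = ds.copy()
    if set(params) == {_GLOBAL_GROUP}:
        lo, hi = params[_GLOBAL_GROUP]
        out["hr_bpm"] = out["hr_bpm"] * (hi - lo) + lo
        return out
    for name, (lo, hi) in params.items():
        idx = out.index[out["subject_id"].astype(str) == name]
        out.loc[idx, "hr_bpm"] = out.loc[idx, "hr_bpm"] * (hi - lo) + lo
    return out


def oversample_gaussian(ds: pd.DataFrame, cfg: BalanceConfig) -> pd.DataFrame:
    """Equalize class sizes with Gaussian noisy replicates.

    Every observed exposure level ends up with exactly ``target_count``
    rows (default: the majority-class count). Deterministic given
    ``cfg.seed``; classes are processed in label order.
    """
    validate_labeled(ds)
    if len(ds) == 0:
        raise ValueError("empty dataset")
    vals = ds["hr_bpm"].to_numpy(dtype=float)
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("oversampling expects HR scaled to [0, 1]; run minmax_scale first")
    counts = ds["level"].value_counts()
    if (counts == 0).any():
        raise ValueError("cannot oversample an empty class")
    target = int(cfg.target_count) if cfg.target_count is not None else int(counts.max())
    if target < counts.max():
        raise ValueError(f"target_count {target} below majority class count {counts.max()}")
    rng = np.random.default_rng(cfg.seed)
    pieces = [ds]
    for level in sorted(counts.index):
        n = int(counts[level])
        k = target - n
        if k == 0:
            continue
        src = ds[ds["level"] == level]
        picked = src.iloc[rng.integers(0, n, size=k)].copy()
        noisy = picked["hr_bpm"].to_numpy() + rng.normal(0.0, cfg.noise_sd, size=k)
        picked["hr_bpm"] = np.clip(noisy, 0.0, 1.0)
        picked["is_replicate"] = True
        pieces.append(picked)
    if len(pieces) == 1:
        return ds.copy()
    return pd.concat(pieces, ignore_index=True)
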