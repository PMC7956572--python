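"""Delimited-text and JSON I/O for the pipeline's intermediate products.

All tabular files are header-bearing CSV; ECG files carry a JSON
sidecar (``<file>.meta.json``) with the sampling rate and provenance so
a record can be reloaded without external knowledge.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import LABEL_COLUMNS, CoSeries, EcgRecord, HrSeries, validate_labeled

PathLike = Union[str, Path]


def write_ecg(ecg: EcgRecord, path: PathLike, meta: Optional[dict] = None) -> None:
    path = Path(path)
    t = np.arange(len(ecg.samples)) / ecg.rate
    pd.DataFrame({"time_s": t, "mv": ecg.samples}).to_csv(path, index=False)
    sidecar = {"rate": ecg.rate, "subject_id": ecg.subject_id}
    if meta:
        sidecar.update(meta)
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_ecg(path: PathLike, rate: Optional[float] = None) -> EcgRecord:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".meta.json")
    subject = "S0"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        rate = rate if rate is not None else meta.get("rate")
        subject = meta.get("subject_id", subject)
    if rate is None:
        raise ValueError("sampling rate not given and no metadata sidecar found")
    return EcgRecord(samples=df["mv"].to_numpy(), rate=float(rate), subject_id=subject)


def write_hr(hr: HrSeries, path: PathLike) -> None:
    pd.DataFrame({"t_s": hr.t, "bpm": hr.bpm, "subject_id": hr.subject_id}).to_csv(path, index=False)


def read_hr(path: PathLike) -> HrSeries:
    df = pd.read_csv(path)
    subject = str(df["subject_id"].iloc[0]) if len(df) else "S0"
    return HrSeries(bpm=df["bpm"].to_numpy(), t=df["t_s"].to_numpy(), subject_id=subject)


def write_co(co: CoSeries, path: PathLike) -> None:
    pd.DataFrame({"time_s": co.t, "ppm": co.ppm, "subject_id": co.subject_id}).to_csv(path, index=False)


def read_co(path: PathLike, cadence_s: Optional[float] = None) -> CoSeries:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if cadence_s is None:
        cadence_s = float(np.median(np.diff(t))) if len(t) > 1 else 60.0
    subject = str(df["subject_id"].iloc[0]) if "subject_id" in df and len(df) else "S0"
    return CoSeries(t=t, ppm=df["ppm"].to_numpy(), cadence_s=cadence_s, subject_id=subject)


def write_labeled(ds: pd.DataFrame, path: PathLike) -> None:
    validate_labeled(ds)[LABEL_COLUMNS].to_csv(path, index=False)


def read_labeled(path: PathLike) -> pd.DataFrame:
    return validate_labeled(pd.read_csv(path))


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json(orient="split"))
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        return super().default(o)


def write_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report, indent=2, cls=_ReportEncoder) + "\n")


def read_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
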