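"""End-to-end orchestration: simulate → label → stats → balance → classify.

One :class:`~coexp.config.RunConfig` plus one seed fully determines a
run; the emitted report embeds the resolved config and all derived
seeds, so a rerun with the same inputs reproduces the report
bit-identically. Stage failures are re-raised as :class:`PipelineError`
naming the stage.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, replace
from typing import Dict, List

import numpy as np
import pandas as pd

from . import classify, ecg, labeling, resampling, stats, synthetic
from .config import RunConfig
from .core import HrSeries

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _derive_seeds(master: int, n_subjects: int) -> Dict[str, object]:
    state = np.random.SeedSequence(master).generate_state(2 * n_subjects + 2) % (2**31)
    return {
        "co": [int(s) for s in state[:n_subjects]],
        "hr": [int(s) for s in state[n_subjects : 2 * n_subjects]],
        "balance": int(state[-2]),
        "ensemble": int(state[-1]),
    }


def _simulate_subject(cfg: RunConfig, subject: str, co_seed: int, hr_seed: int) -> tuple:
    scen = cfg.scenario
    co = synthetic.generate_co_profile(scen, subject, seed=co_seed)
    hr = synthetic.generate_hr_trajectory(scen, co, seed=hr_seed)
    if cfg.ecg_synthesis:
        record = synthetic.generate_ecg_from_hr(hr, scen)
        filtered = ecg.remove_baseline(ecg.lowpass_filter(record))
        peaks = ecg.detect_r_peaks(filtered)
        hr = ecg.compute_hr(peaks, subject_id=subject)
    return co, hr


def _stats_stage(ds: pd.DataFrame, subjects: List[str], alpha: float) -> dict:
    observed = sorted(ds["level"].unique())
    if len(observed) < 2:
        raise ValueError("fewer than two exposure levels observed")
    out: dict = {"boxplot_by_level": stats.level_boxplot_summary(ds)}
    lillie = {}
    for subject, grp in ds.groupby("subject_id"):
        stat, p = stats.lilliefors_test(grp["hr_bpm"].to_numpy())
        lillie[str(subject)] = {"statistic": stat, "p_value": p, "normal": bool(p >= alpha)}
    out["lilliefors_by_subject"] = lillie
    if len(subjects) >= 3 and all(l in observed for l in ("L1", "L2", "L3")):
        combos = stats.build_combinations(subjects[:3])
        combo_reports = []
        for i, combo in enumerate(combos, start=1):
            groups, labels = [], []
            for level, subject in combo.items():
                sel = ds[(ds["subject_id"] == subject) & (ds["level"] == level)]
                groups.append(sel["hr_bpm"].to_numpy())
                labels.append(level)
            if any(len(g) == 0 for g in groups):
                combo_reports.append({"combination": i, "assignment": combo, "skipped": "empty group"})
                continue
            kw = stats.kruskal_wallis(groups, labels=labels)
            pairs = stats.multicompare(kw, alpha=alpha)
            combo_reports.append(
                {
                    "combination": i,
                    "assignment": combo,
                    "kw": asdict(kw),
                    "pairwise": [asdict(p) for p in pairs],
                    "intervals": stats.group_rank_intervals(kw, alpha=alpha),
                }
            )
        out["combinations"] = combo_reports
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis on a synthetic campaign; returns the report."""
    scen = cfg.scenario
    subjects = [f"FF{i + 1}" for i in range(scen.n_subjects)]
    seeds = _derive_seeds(cfg.seed, scen.n_subjects)
    report: dict = {"config": asdict(cfg), "seeds": seeds, "stage_counts": {}}

    def _count(stage: str, n: int) -> None:
        logger.info("stage %s: %d rows", stage, n)
        report["stage_counts"][stage] = n

    try:
        labeled_parts = []
        for subject, cs, hs in zip(subjects, seeds["co"], seeds["hr"]):
            co, hr = _simulate_subject(cfg, subject, cs, hs)
            labeled_parts.append(labeling.label_hr(hr, co))
        ds = pd.concat(labeled_parts, ignore_index=True)
        _count("simulate+label", len(ds))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate+label", e) from e

    try:
        tables = labeling.tabulate_levels(ds)
        report["level_tables"] = {k: v for k, v in tables.items()}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("tabulate", e) from e

    try:
        report["stats"] = _stats_stage(ds, subjects, cfg.alpha)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", e) from e

    try:
        scaled, scale_params = resampling.minmax_scale(ds, per_subject=True)
        report["scale_params"] = scale_params
        bal_cfg = replace(cfg.balance, seed=seeds["balance"])
        ens_cfg = replace(cfg.ensemble, seed=seeds["ensemble"])
        if cfg.mode == "faithful":
            balanced = resampling.oversample_gaussian(scaled, bal_cfg)
            _count("oversample", len(balanced))
            cv_error, cv_cm = classify.cross_validate(balanced, ens_cfg)
            train, test = classify.stratified_split(balanced, ens_cfg)
        else:  # leakage_safe: split originals first, oversample train only
            cv_error, cv_cm = classify.cross_validate(scaled, ens_cfg, balance=bal_cfg)
            train_raw, test = classify.stratified_split(scaled, ens_cfg)
            train = resampling.oversample_gaussian(train_raw, bal_cfg)
            _count("oversample(train)", len(train))
        _count("train", len(train))
        _count("test", len(test))
        model = classify.fit_ensemble(train, ens_cfg)
        test_cm = classify.ConfusionMatrix.from_predictions(
            test["level"].to_numpy(), classify.predict(model, test), cv_cm.labels
        )
        report["cv"] = {
            "error_rate_pct": cv_error * 100.0,
            "confusion": cv_cm.counts,
            "labels": cv_cm.labels,
            "metrics": _metrics_dict(classify.compute_metrics(cv_cm)),
        }
        report["test"] = {
            "confusion": test_cm.counts,
            "labels": test_cm.labels,
            "metrics": _metrics_dict(classify.compute_metrics(test_cm)),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classification", e) from e

    return report


def _metrics_dict(m: classify.ClassMetrics) -> dict:
    return {
        "per_class": m.per_class,
        "accuracy_pct": m.accuracy_pct,
        "macro_precision_pct": m.macro_precision_pct,
        "macro_recall_pct": m.macro_recall_pct,
        "macro_f1_pct": m.macro_f1_pct,
        "error_rate_pct": m.error_rate_pct,
    }


def hr_series_from_frame(df: pd.DataFrame, subject_id: str) -> HrSeries:
    """Convenience: an HrSeries view of one subject's labeled rows."""
    sel = df[df["subject_id"] == subject_id]
    return HrSeries(bpm=sel["hr_bpm"].to_numpy(), t=sel["t_s"].to_numpy(), subject_id=subject_id)
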