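"""Bagged-tree classification of CO exposure level from heart rate.

The classifier is an ensemble of 100 bootstrap-aggregated classification
trees with majority voting, fitted on a single predictor — the scaled
heart rate. With one feature, per-split random predictor selection is a
no-op, so a random forest and plain tree bagging coincide; tree depth is
left unlimited. Evaluation follows the study protocol: a pooled
confusion matrix from stratified 10-fold cross-validation, and a
stratified 70/30 hold-out split with per-class precision, recall and F1

    Precision = TP / (TP + FP),   Recall = TP / (TP + FN),
    F1 = 2 * Precision * Recall / (Precision + Recall),

reported as percentages together with macro averages and accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .config import BalanceConfig, EnsembleConfig
from .core import validate_labeled
from .resampling import oversample_gaussian


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true levels, columns predicted levels."""

    counts: np.ndarray
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.labels = tuple(self.labels)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.labels):
            raise ValueError("label count must match matrix size")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels: Tuple[str, ...]) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, labels=labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    """Per-class counts/metrics plus macro averages, all rates in %."""

    per_class: pd.DataFrame  # index: class; columns: tp, fp, fn, tn, precision, recall, f1
    accuracy_pct: float
    macro_precision_pct: float
    macro_recall_pct: float
    macro_f1_pct: float
    error_rate_pct: float


def _features(ds: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    validate_labeled(ds)
    return ds[["hr_bpm"]].to_numpy(dtype=float), ds["level"].to_numpy()


def fit_ensemble(train: pd.DataFrame, cfg: EnsembleConfig):
    """Fit the configured tree ensemble on the scaled-HR feature.

    ``bagging`` (the faithful configuration) uses bootstrap-aggregated
    trees with majority voting; ``adaboost`` is exposed for method
    comparison with library-default boosting parameters. Deterministic
    given ``cfg.seed``.
    """
    X, y = _features(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if cfg.method == "bagging":
        model = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1)
    elif cfg.method == "adaboost":
        model = AdaBoostClassifier(n_estimators=cfg.n_trees, random_state=cfg.seed)
    else:
        raise NotImplementedError(
            "random-undersampling boosting is not available in this environment"
        )
    model.fit(X, y)
    return model


def predict(model, ds: pd.DataFrame) -> np.ndarray:
    X, _ = _features(ds)
    return model.predict(X)


def stratified_split(ds: pd.DataFrame, cfg: EnsembleConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split preserving the class distribution.

    The train size is ``round(train_fraction * len(ds))``; per-class
    sizes are floored and the shortfall is handed to the classes with
    the largest fractional remainders, so every class share stays
    within one sample of the global fraction. Rows are shuffled within
    class (seeded) before assignment.
    """
    validate_labeled(ds)
    counts = ds["level"].value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 rows to split")
    n_train_total = int(round(cfg.train_fraction * len(ds)))
    classes = sorted(counts.index)
    exact = np.array([cfg.train_fraction * counts[c] for c in classes])
    base = np.floor(exact).astype(int)
    short = n_train_total - base.sum()
    order = np.lexsort((np.arange(len(classes)), -(exact - base)))
    take = base.copy()
    take[order[:short]] += 1
    rng = np.random.default_rng(cfg.seed)
    train_parts, test_parts = [], []
    for c, n_take in zip(classes, take):
        idx = ds.index[ds["level"] == c].to_numpy()
        rng.shuffle(idx)
        train_parts.append(ds.loc[idx[:n_take]])
        test_parts.append(ds.loc[idx[n_take:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def cross_validate(
    ds: pd.DataFrame,
    cfg: EnsembleConfig,
    balance: Optional[BalanceConfig] = None,
) -> Tuple[float, ConfusionMatrix]:
    """Stratified k-fold CV; pooled out-of-fold confusion matrix.

    With ``balance`` given, oversampling is redone inside each training
    fold (leakage-safe evaluation on untouched held-out originals);
    without it the input is used as-is, matching a protocol that
    oversamples before splitting.

    Returns ``(error_rate, matrix)`` with the error rate as a fraction.
    """
    X, y = _features(ds)
    counts = pd.Series(y).value_counts()
    if (counts < cfg.cv_folds).any():
        raise ValueError("every class must have at least cv_folds rows")
    labels = tuple(sorted(counts.index))
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    y_pred = np.empty(len(ds), dtype=object)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        train_df = ds.iloc[tr]
        if balance is not None:
            fold_cfg = BalanceConfig(
                noise_sd=balance.noise_sd,
                seed=(balance.seed + 7919 * fold) % (2**31),
                target_count=balance.target_count,
            )
            train_df = oversample_gaussian(train_df, fold_cfg)
        model = fit_ensemble(train_df, cfg)
        y_pred[te] = model.predict(X[te])
    cm = ConfusionMatrix.from_predictions(y, y_pred, labels)
    error_rate = 1.0 - np.trace(cm.counts) / cm.total
    return float(error_rate), cm


def compute_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class TP/FP/FN/TN and precision/recall/F1 (%) from a matrix.

    A class with no true rows has undefined recall (likewise precision
    with no predictions); these are reported as 0 with a warning so
    batch evaluations keep running.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)
    col = counts.sum(axis=0).astype(float)
    fp = col - tp
    fn = row - tp
    tn = total - row - col + tp

    def _ratio(num, den, what):
        out = np.zeros_like(num)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for i in np.flatnonzero(~ok):
            warnings.warn(f"{what} undefined for class {cm.labels[i]}; reporting 0", stacklevel=3)
        return out

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    pr_sum = precision + recall
    f1 = np.where(pr_sum > 0, 2.0 * precision * recall / np.where(pr_sum > 0, pr_sum, 1.0), 0.0)
    per_class = pd.DataFrame(
        {
            "tp": tp.astype(int),
            "fp": fp.astype(int),
            "fn": fn.astype(int),
            "tn": tn.astype(int),
            "precision": precision * 100.0,
            "recall": recall * 100.0,
            "f1": f1 * 100.0,
        },
        index=list(cm.labels),
    )
    accuracy = float(np.trace(counts) / total * 100.0)
    return ClassMetrics(
        per_class=per_class,
        accuracy_pct=accuracy,
        macro_precision_pct=float(per_class["precision"].mean()),
        macro_recall_pct=float(per_class["recall"].mean()),
        macro_f1_pct=float(per_class["f1"].mean()),
        error_rate_pct=100.0 - accuracy,
    )


def max_hr_limits(
    age_max_hr: float = 220.0,
    intense_fraction: float = 0.70,
    rest_max: float = 100.0,
) -> Tuple[float, float]:
    """Quality-control heart-rate limits (rest ceiling, intense-activity ceiling).

    During intense activity HR should stay below ``intense_fraction`` of
    the maximum HR; with the conventional maximum of 220 bpm and a 70%
    fraction the intense-activity ceiling is 154 bpm, while the resting
    ceiling is 100 bpm.
    """
    if not 0 < intense_fraction <= 1:
        raise ValueError("intense_fraction must lie in (0, 1]")
    return float(rest_max), float(intense_fraction * age_max_hr)
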