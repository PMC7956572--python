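"""Nonparametric group comparison of heart rate across CO exposure levels.

The analysis protocol is: screen each sample for normality with the
Lilliefors test; since heart-rate data are typically non-normal, compare
the exposure-level groups with the Kruskal-Wallis rank test; when the
omnibus test rejects, locate the differing pairs with a rank-based
multiple comparison whose critical values come from the studentized
range (Tukey-Kramer on mean ranks). To keep the three level groups
statistically independent when pooling subjects, each group is drawn
from a *different* subject, and the three cyclic level-to-subject
assignments are each tested.

The Kruskal-Wallis statistic with midranks and tie correction:

    H = [ 12 / (N (N+1)) * sum_i n_i (rbar_i - (N+1)/2)^2 ] / C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N),

compared against a chi-square with k-1 degrees of freedom. The pairwise
comparison of groups a, b uses

    q_ab = |rbar_a - rbar_b| / sqrt( (V/2) (1/n_a + 1/n_b) ),
    V    = N (N+1) / 12  -  sum_t (t^3 - t) / (12 (N - 1)),

referred to the studentized range with k groups and infinite df, which
is what the familiar interactive multiple-comparison display computes
for rank data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors


@dataclass
class KwResult:
    """Kruskal-Wallis outcome plus what the multiple comparison needs."""

    H: float
    p_value: float
    group_labels: Tuple[str, ...]
    n_per_group: Tuple[int, ...]
    group_mean_ranks: Tuple[float, ...]
    grand_n: int
    tie_sum: float  # sum over tie groups of (t^3 - t)

    @property
    def k(self) -> int:
        return len(self.group_labels)


@dataclass
class PairwiseComparison:
    """Rank-mean difference between two groups with its comparison interval."""

    group_a: str
    group_b: str
    rank_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


def lilliefors_statistic(values: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to a normal with estimated mean/sd."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max((ecdf_hi - cdf).max(), (cdf - ecdf_lo).max()))


def lilliefors_test(
    values: Sequence[float],
    method: str = "table",
    n_mc: int = 10000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Normality screen with estimated parameters.

    ``method="table"`` uses the standard approximation table;
    ``method="mc"`` estimates the null distribution of the statistic by
    seeded Monte Carlo (``n_mc`` standard-normal samples of the same
    size) and reports ``(1 + #{D* >= D}) / (n_mc + 1)``.

    Returns ``(statistic, p_value)``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("Lilliefors test needs at least 5 observations")
    if x.min() == x.max():
        raise ValueError("Lilliefors test undefined for constant input")
    if method == "table":
        stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    d_obs = lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    n = len(x)
    exceed = 0
    chunk = max(1, int(2e6 // n))
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        sims = np.sort(rng.normal(size=(m, n)), axis=1)
        z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf(z)
        hi = (np.arange(1, n + 1) / n - cdf).max(axis=1)
        lo = (cdf - np.arange(0, n) / n).max(axis=1)
        exceed += int((np.maximum(hi, lo) >= d_obs).sum())
        done += m
    return d_obs, (1 + exceed) / (n_mc + 1)


def build_combinations(subjects: Sequence[str]) -> List[Dict[str, str]]:
    """The three cyclic level-to-subject assignments.

    With subjects (A, B, C) the combinations are
    ``{L1: A, L2: B, L3: C}``, ``{L1: B, L2: C, L3: A}`` and
    ``{L1: C, L2: A, L3: B}`` — each level group drawn from a different
    subject so the three samples are independent.
    """
    subjects = list(subjects)
    if len(subjects) != 3:
        raise ValueError("independence combinations require exactly 3 subjects")
    if len(set(subjects)) != 3:
        raise ValueError("subject labels must be distinct")
    levels = ("L1", "L2", "L3")
    return [
        {level: subjects[(shift + j) % 3] for j, level in enumerate(levels)}
        for shift in range(3)
    ]


def kruskal_wallis(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> KwResult:
    """Tie-corrected Kruskal-Wallis test over ``groups``.

    Keeps the per-group mean ranks and the tie term so
    :func:`multicompare` can run on the same ranking.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    if n_total < 5:
        raise ValueError("need at least 5 observations in total")
    if pooled.min() == pooled.max():
        raise ValueError("all values identical across all groups")
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float((tie_counts**3 - tie_counts).sum())
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        n_i * (rbar - (n_total + 1) / 2.0) ** 2 for n_i, rbar in zip(sizes, mean_ranks)
    )
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    h /= correction
    p = float(sps.chi2.sf(h, df=len(arrays) - 1))
    if labels is None:
        labels = [f"G{i + 1}" for i in range(len(arrays))]
    return KwResult(
        H=float(h),
        p_value=p,
        group_labels=tuple(str(l) for l in labels),
        n_per_group=tuple(sizes),
        group_mean_ranks=tuple(float(r) for r in mean_ranks),
        grand_n=n_total,
        tie_sum=tie_sum,
    )


def _rank_variance(kw: KwResult) -> float:
    n = kw.grand_n
    return n * (n + 1) / 12.0 - kw.tie_sum / (12.0 * (n - 1))


def multicompare(kw: KwResult, alpha: float = 0.05, bonferroni: bool = False) -> List[PairwiseComparison]:
    """All pairwise rank-mean comparisons after a Kruskal-Wallis test.

    Default critical values come from the studentized range with k
    groups and infinite df (Tukey-Kramer on mean ranks); pass
    ``bonferroni=True`` for normal-approximation z tests at
    ``alpha / C`` over the C pairs instead. In both variants the
    interval on the rank difference excludes 0 exactly when
    ``p < alpha`` (consistency by construction).
    """
    if kw.k < 2:
        raise ValueError("need at least two groups to compare")
    v = _rank_variance(kw)
    n_pairs = kw.k * (kw.k - 1) // 2
    out: List[PairwiseComparison] = []
    for i, j in combinations(range(kw.k), 2):
        diff = kw.group_mean_ranks[i] - kw.group_mean_ranks[j]
        inv_n = 1.0 / kw.n_per_group[i] + 1.0 / kw.n_per_group[j]
        if bonferroni:
            se = np.sqrt(v * inv_n)
            p = float(min(1.0, n_pairs * 2.0 * sps.norm.sf(abs(diff) / se)))
            crit = float(sps.norm.ppf(1.0 - alpha / (2.0 * n_pairs)) * se)
        else:
            se_q = np.sqrt(v / 2.0 * inv_n)
            q = abs(diff) / se_q
            p = float(sps.studentized_range.sf(q, kw.k, np.inf))
            crit = float(sps.studentized_range.ppf(1.0 - alpha, kw.k, np.inf) * se_q)
        out.append(
            PairwiseComparison(
                group_a=kw.group_labels[i],
                group_b=kw.group_labels[j],
                rank_diff=float(diff),
                ci_low=float(diff - crit),
                ci_high=float(diff + crit),
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return out


def group_rank_intervals(kw: KwResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group comparison intervals around the mean ranks.

    Half-widths are chosen so that, for equal group sizes, two groups'
    intervals are disjoint exactly when their pairwise comparison is
    significant — the familiar graphical multiple-comparison display.
    """
    v = _rank_variance(kw)
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, kw.k, np.inf))
    rows = []
    for label, n_g, rbar in zip(kw.group_labels, kw.n_per_group, kw.group_mean_ranks):
        half = q_crit / 2.0 * np.sqrt(v / n_g)
        rows.append({"group": label, "mean_rank": rbar, "low": rbar - half, "high": rbar + half, "n": n_g})
    return pd.DataFrame(rows)


def level_boxplot_summary(ds: pd.DataFrame, per_subject: bool = False) -> pd.DataFrame:
    """Five-number box-plot summary of HR per exposure level.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme observation within 1.5 IQR of the box, and everything
    beyond is counted as an outlier.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    keys = ["subject_id", "level"] if per_subject else ["level"]
    rows = []
    for key, grp in ds.groupby(keys, observed=True):
        vals = grp["hr_bpm"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            {
                "n": len(vals),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "n_outliers": int(len(vals) - len(inside)),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
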