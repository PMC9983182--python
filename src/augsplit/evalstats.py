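"""Pooled cross-validation statistics.

Metrics are *pooled* (micro-averaged) across folds: the per-fold confusion
counts are summed and each metric is a single proportion
``successes/trials``::

    accuracy    = sum(TP_k + TN_k) / sum(TP_k + TN_k + FP_k + FN_k)
    sensitivity = sum(TP_k)        / sum(TP_k + FN_k)
    specificity = sum(TN_k)        / sum(TN_k + FP_k)

with exact (Clopper-Pearson) binomial 95% confidence intervals built from
those same success/trial counts.  ROC AUC is computed on the prediction
probabilities of all folds pooled together — which penalizes models whose
probability calibration drifts between folds, unlike a mean of per-fold
AUCs.  Per-fold scalar measurements (epoch counts, training times) get
t-based confidence intervals with k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harness import ConfusionCounts, FoldResult

__all__ = [
    "UndefinedMetricError",
    "ProportionEstimate",
    "AucEstimate",
    "MeanEstimate",
    "PooledMetrics",
    "TimeCostResult",
    "exact_binomial_ci",
    "pooled_proportion_metrics",
    "pooled_roc_auc",
    "mean_with_t4_ci",
    "time_cost_correlation",
]


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero (e.g. no positives in any test set)."""


def exact_binomial_ci(successes: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    By convention the lower bound is 0 when ``successes == 0`` and the upper
    bound is 1 when ``successes == trials``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    res = stats.binomtest(successes, trials).proportion_ci(
        confidence_level=1.0 - alpha, method="exact"
    )
    return float(res.low), float(res.high)


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its success/trial counts and exact CI bounds."""

    successes: int
    trials: int
    point: float
    ci_low: float
    ci_high: float

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


def _proportion(successes: int, trials: int, alpha: float, name: str) -> ProportionEstimate:
    if trials == 0:
        raise UndefinedMetricError(f"{name} is undefined: its denominator is zero")
    low, high = exact_binomial_ci(successes, trials, alpha)
    return ProportionEstimate(successes, trials, successes / trials, low, high)


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class MeanEstimate:
    mean: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class PooledMetrics:
    """Summed confusion counts with lazily computed proportion metrics.

    Accessing a metric whose denominator is zero raises
    :class:`UndefinedMetricError`; the other metrics remain available.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n_folds: int
    alpha: float = 0.05
    roc_auc: AucEstimate | None = None

    @property
    def accuracy(self) -> ProportionEstimate:
        return _proportion(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn,
                           self.alpha, "accuracy")

    @property
    def sensitivity(self) -> ProportionEstimate:
        return _proportion(self.tp, self.tp + self.fn, self.alpha, "sensitivity")

    @property
    def specificity(self) -> ProportionEstimate:
        return _proportion(self.tn, self.tn + self.fp, self.alpha, "specificity")


def _as_confusions(folds) -> list[ConfusionCounts]:
    out = []
    for f in folds:
        if isinstance(f, ConfusionCounts):
            out.append(f)
        elif isinstance(f, FoldResult):
            raise TypeError("pass ConfusionCounts (pick a test condition from "
                            "FoldResult.tests first)")
        else:
            out.append(ConfusionCounts(*f))
    return out


def pooled_proportion_metrics(folds, alpha: float = 0.05) -> PooledMetrics:
    """Micro-averaged accuracy/sensitivity/specificity over k folds.

    ``folds`` is a sequence of per-fold confusion counts (or ``(tp, tn, fp,
    fn)`` tuples).  Equivalent to computing one confusion matrix over the
    concatenation of all folds' predictions.
    """
    confs = _as_confusions(folds)
    if not confs:
        raise ValueError("need at least one fold")
    return PooledMetrics(
        tp=sum(c.tp for c in confs),
        tn=sum(c.tn for c in confs),
        fp=sum(c.fp for c in confs),
        fn=sum(c.fn for c in confs),
        n_folds=len(confs),
        alpha=alpha,
    )


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rank_all = stats.rankdata(allv)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    # placement values (structural components)
    v10 = (rank_all[:m] - rank_pos) / n          # per positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m    # per negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def pooled_roc_auc(
    probabilities,
    labels,
    alpha: float = 0.05,
    ci_method: str = "delong",
) -> AucEstimate:
    """ROC AUC of pooled probabilities, with a 95% CI.

    The AUC is the probability that a random positive outranks a random
    negative, ties counting one half.  ``ci_method`` is ``"delong"``
    (variance-based, the default) or ``"exact-binomial"`` (Clopper-Pearson
    treating the AUC as a proportion of concordant positive-negative pairs,
    rounded to the nearest pair count).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have the same length")
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise UndefinedMetricError("ROC AUC is undefined: the pool has one class only")
    # Mann-Whitney form via ranks (ties count one half)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    if ci_method == "delong":
        se = float(np.sqrt(_delong_variance(pos, neg)))
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        low, high = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif ci_method == "exact-binomial":
        low, high = exact_binomial_ci(int(round(auc * m * n)), m * n, alpha)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return AucEstimate(float(auc), float(low), float(high), ci_method, m, n)


def mean_with_t4_ci(values, alpha: float = 0.05) -> MeanEstimate:
    """Mean of per-fold measurements with a t-based CI (k-1 df; 4 df at k=5)."""
    v = np.asarray(values, dtype=float)
    k = len(v)
    if k < 2:
        raise UndefinedMetricError("a t-based CI needs at least 2 values")
    mean = float(v.mean())
    half = float(stats.t.ppf(1.0 - alpha / 2.0, k - 1) * v.std(ddof=1) / np.sqrt(k))
    return MeanEstimate(mean, mean - half, mean + half, k)


@dataclass(frozen=True)
class TimeCostResult:
    """Pearson correlation of a performance metric against log mean training time."""

    metric_name: str
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n_groups: int


def time_cost_correlation(
    metric_values,
    mean_times,
    metric_name: str = "metric",
) -> TimeCostResult:
    """Correlate a metric with the natural log of mean training time.

    One point per result group within a classifier stratum; callers must
    already have excluded the augment-first (way F) groups and the
    non-augmented-test metrics.  The log transform reflects that the metric
    is bounded above while training time is not.
    """
    y = np.asarray(metric_values, dtype=float)
    t = np.asarray(mean_times, dtype=float)
    if len(y) != len(t):
        raise ValueError("metric_values and mean_times must have the same length")
    if len(y) < 3:
        raise ValueError("need at least 3 groups per stratum")
    if np.any(t <= 0):
        raise ValueError("training times must be strictly positive")
    x = np.log(t)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise UndefinedMetricError("correlation undefined: zero variance")
    r, p = stats.pearsonr(y, x)
    fit = stats.linregress(x, y)
    return TimeCostResult(metric_name, float(r), float(p),
                          float(fit.slope), float(fit.intercept), len(y))


def filter_time_cost_groups(rows) -> list:
    """Keep only the groups entering the time-cost analysis.

    Drops way-F (augment-first) groups and non-augmented-test groups; with
    all 11 evaluation configurations per classifier this leaves 5 per
    classifier (20 for four classifiers).  ``rows`` is an iterable of
    objects or mappings with ``way`` and ``test_condition`` fields.
    """
    def get(r, name):
        return r[name] if isinstance(r, dict) else getattr(r, name)
    return [r for r in rows
            if get(r, "way") != "F" and get(r, "test_condition") == "augmented"]
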