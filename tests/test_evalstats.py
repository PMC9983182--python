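"""Pooled metrics, exact intervals, pooled AUC — each against an
independent brute-force oracle."""

import numpy as np
import pytest
from scipy import stats

from augsplit.evalstats import (
    UndefinedMetricError,
    exact_binomial_ci,
    filter_time_cost_groups,
    mean_with_t4_ci,
    pooled_proportion_metrics,
    pooled_roc_auc,
    time_cost_correlation,
)
from augsplit.harness import ConfusionCounts


# --- pooled proportions -----------------------------------------------------

def test_perfect_classifier_all_metrics_one():
    folds = [ConfusionCounts(10, 10, 0, 0)] * 5
    m = pooled_proportion_metrics(folds)
    assert m.accuracy.point == m.sensitivity.point == m.specificity.point == 1.0
    assert m.accuracy.ci_high == 1.0


def test_printed_formula_arithmetic():
    folds = [ConfusionCounts(3, 2, 1, 2)] * 5
    m = pooled_proportion_metrics(folds)
    assert m.accuracy.point == pytest.approx(25 / 40)
    assert m.sensitivity.point == pytest.approx(15 / 25)
    assert m.specificity.point == pytest.approx(10 / 15)


def test_pooled_equals_concatenation_oracle():
    """Micro-averaged pooling must equal the confusion matrix of all folds'
    predictions concatenated (100 random fold sets)."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        k = rng.integers(2, 7)
        folds = [ConfusionCounts(*rng.integers(0, 30, size=4)) for _ in range(k)]
        # oracle: concatenate predictions record by record, recount
        y_true, y_pred = [], []
        for c in folds:
            y_true += [1] * c.tp + [0] * c.tn + [0] * c.fp + [1] * c.fn
            y_pred += [1] * c.tp + [0] * c.tn + [1] * c.fp + [0] * c.fn
        y_true, y_pred = np.array(y_true), np.array(y_pred)
        m = pooled_proportion_metrics(folds)
        if (y_true == y_pred).size:
            assert m.accuracy.point == pytest.approx((y_true == y_pred).mean())
        if (y_true == 1).any():
            assert m.sensitivity.point == pytest.approx(
                y_pred[y_true == 1].mean()
            )
        if (y_true == 0).any():
            assert m.specificity.point == pytest.approx(
                1 - y_pred[y_true == 0].mean()
            )


def test_zero_denominator_raises_for_that_metric_only():
    m = pooled_proportion_metrics([ConfusionCounts(0, 5, 2, 0)] * 3)
    assert m.accuracy.point == pytest.approx(15 / 21)
    with pytest.raises(UndefinedMetricError, match="sensitivity"):
        m.sensitivity
    assert m.specificity.point == pytest.approx(15 / 21)


# --- Clopper-Pearson --------------------------------------------------------

def _cp_oracle(successes, trials, alpha=0.05, tol=1e-9):
    """Tail-sum bisection: invert the exact binomial tail probabilities."""
    def upper_tail(p):  # P(X >= successes | p)
        return stats.binom.sf(successes - 1, trials, p)

    def lower_tail(p):  # P(X <= successes | p)
        return stats.binom.cdf(successes, trials, p)

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    low = 0.0 if successes == 0 else bisect(upper_tail, alpha / 2, 0.0, 1.0)
    high = 1.0 if successes == trials else bisect(
        lambda p: -lower_tail(p), -alpha / 2, 0.0, 1.0
    )
    return low, high


@pytest.mark.parametrize("s,n", [(5, 10), (0, 20), (20, 20), (1, 7), (37, 40), (99, 200)])
def test_clopper_pearson_matches_tail_sum_bisection(s, n):
    low, high = exact_binomial_ci(s, n)
    olow, ohigh = _cp_oracle(s, n)
    assert low == pytest.approx(olow, abs=1e-6)
    assert high == pytest.approx(ohigh, abs=1e-6)


def test_clopper_pearson_boundary_conventions():
    assert exact_binomial_ci(0, 20)[0] == 0.0
    assert exact_binomial_ci(20, 20)[1] == 1.0


def test_clopper_pearson_invalid_counts():
    with pytest.raises(ValueError):
        exact_binomial_ci(5, 4)
    with pytest.raises(ValueError):
        exact_binomial_ci(-1, 4)


def test_clopper_pearson_coverage_is_conservative():
    """Over simulated binomial draws the exact interval must cover the true
    p at >= 95% (Clopper-Pearson is conservative by construction)."""
    rng = np.random.default_rng(7)
    for p in (0.1, 0.5, 0.9):
        for n in (20, 200):
            draws = rng.binomial(n, p, size=2000)
            covered = 0
            for s in np.unique(draws):
                lo, hi = exact_binomial_ci(int(s), n)
                covered += ((lo <= p) & (p <= hi)) * (draws == s).sum()
            assert covered / 2000 >= 0.95


def test_eightfold_counts_shrink_ci_toward_sqrt8():
    lo1, hi1 = exact_binomial_ci(80, 100)
    lo8, hi8 = exact_binomial_ci(640, 800)
    ratio = (hi8 - lo8) / (hi1 - lo1)
    assert ratio < 0.5
    assert ratio == pytest.approx(1 / np.sqrt(8), abs=0.03)


# --- pooled ROC AUC ---------------------------------------------------------

def _auc_pair_oracle(probs, labels):
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_separation():
    p = np.array([0.9, 0.8, 0.2, 0.1])
    y = np.array([1, 1, 0, 0])
    assert pooled_roc_auc(p, y).auc == 1.0


def test_auc_all_ties_is_half():
    p = np.full(10, 0.4)
    y = np.array([1, 0] * 5)
    assert pooled_roc_auc(p, y).auc == 0.5


def test_auc_matches_exhaustive_pair_counting():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = rng.integers(4, 51)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        p = rng.choice(np.linspace(0, 1, 11), size=n)  # coarse grid forces ties
        est = pooled_roc_auc(p, y)
        assert est.auc == pytest.approx(_auc_pair_oracle(p, y))
        assert est.ci_low <= est.auc <= est.ci_high


def test_auc_single_class_pool_rejected():
    with pytest.raises(UndefinedMetricError):
        pooled_roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


def test_auc_exact_binomial_mode():
    rng = np.random.default_rng(5)
    p = rng.random(30)
    y = rng.integers(0, 2, size=30)
    y[0], y[1] = 0, 1
    est = pooled_roc_auc(p, y, ci_method="exact-binomial")
    m, n = est.n_positive, est.n_negative
    lo, hi = exact_binomial_ci(int(round(est.auc * m * n)), m * n)
    assert (est.ci_low, est.ci_high) == (lo, hi)


def test_pooling_penalizes_calibration_drift():
    """Two folds, each perfectly separated on its own probability range:
    per-fold AUC = 1 but pooled AUC < 1."""
    f1_p = np.array([0.40, 0.45, 0.30, 0.35])   # positives 0.40/0.45
    f1_y = np.array([1, 1, 0, 0])
    f2_p = np.array([0.90, 0.95, 0.60, 0.55])   # higher range
    f2_y = np.array([1, 1, 0, 0])
    assert pooled_roc_auc(f1_p, f1_y).auc == 1.0
    assert pooled_roc_auc(f2_p, f2_y).auc == 1.0
    pooled = pooled_roc_auc(np.concatenate([f1_p, f2_p]), np.concatenate([f1_y, f2_y]))
    assert pooled.auc < 1.0


# --- t-based CIs ------------------------------------------------------------

def test_t_ci_identical_values_zero_width():
    est = mean_with_t4_ci([3.0] * 5)
    assert est.mean == est.ci_low == est.ci_high == 3.0


def test_t_ci_matches_independent_quantile():
    est = mean_with_t4_ci([1, 2, 3, 4, 5])
    sd = np.std([1, 2, 3, 4, 5], ddof=1)
    half = stats.t.ppf(0.975, 4) * sd / np.sqrt(5)
    assert est.mean == 3.0
    assert est.ci_high - est.mean == pytest.approx(half)


def test_t_ci_width_vanishes_as_alpha_grows():
    wide = mean_with_t4_ci([1, 2, 3, 4, 5], alpha=0.05)
    narrow = mean_with_t4_ci([1, 2, 3, 4, 5], alpha=0.999)
    assert (narrow.ci_high - narrow.ci_low) < 0.01 * (wide.ci_high - wide.ci_low)


def test_t_ci_single_value_rejected():
    with pytest.raises(UndefinedMetricError):
        mean_with_t4_ci([1.0])


# --- time-cost correlation --------------------------------------------------

def test_exact_linear_relation_gives_r_one():
    times = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
    metric = 0.5 + 0.05 * np.log(times)
    res = time_cost_correlation(metric, times)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.p_value < 1e-8
    assert res.slope == pytest.approx(0.05)


def test_correlation_matches_direct_formula():
    rng = np.random.default_rng(11)
    metric = rng.random(5)
    times = rng.random(5) + 0.5
    res = time_cost_correlation(metric, times)
    x = np.log(times)
    r_direct = (((x - x.mean()) * (metric - metric.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((metric - metric.mean()) ** 2).sum()))
    assert res.pearson_r == pytest.approx(r_direct)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        time_cost_correlation([0.5, 0.6], [1.0, 2.0])
    with pytest.raises(ValueError):
        time_cost_correlation([0.5, 0.6, 0.7], [1.0, -2.0, 3.0])
    with pytest.raises(ZeroDivisionError):
        time_cost_correlation([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])


def test_filter_keeps_twenty_of_forty_four():
    rows = []
    for clf in ("m1", "m2", "m3", "m4"):
        for way in "ABCDEF":
            for cond in (["augmented"] if way == "F" else ["plain", "augmented"]):
                rows.append({"classifier": clf, "way": way, "test_condition": cond})
    kept = filter_time_cost_groups(rows)
    assert len(rows) == 44
    assert len(kept) == 20
    assert all(r["way"] != "F" and r["test_condition"] == "augmented" for r in kept)
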