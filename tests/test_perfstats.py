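import numpy as np
import pytest
from scipy import stats

from msiscore import (ConfusionMatrix, accuracy, clopper_pearson,
                      compare_groups, confusion, mann_whitney_auc,
                      purity_score_correlation, roc_auc, sensitivity,
                      specificity)


def _vectors(tp, fn, fp, tn):
    pred = ["MSI-H"] * tp + ["MSS"] * fn + ["MSI-H"] * fp + ["MSS"] * tn
    lab = ["dMMR"] * (tp + fn) + ["pMMR"] * (fp + tn)
    return pred, lab


# ------------------------------------------------------------- confusion

def test_confusion_from_vectors():
    cm = confusion(*_vectors(92, 8, 1, 193))
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (92, 8, 1, 193)
    assert cm.n == 294


def test_confusion_perfect_and_empty():
    cm = confusion(["MSI-H", "MSS"], ["dMMR", "pMMR"])
    assert cm.fn == cm.fp == 0
    assert confusion([], []) == ConfusionMatrix(0, 0, 0, 0)


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion(["MSI-H"], ["dMMR", "pMMR"])


def test_confusion_rejects_failed():
    with pytest.raises(ValueError, match="FAILED"):
        confusion(["FAILED"], ["dMMR"])


# ------------------------------------------------------- proportion metrics

def test_sensitivity_reference_values():
    assert sensitivity(ConfusionMatrix(92, 8, 0, 0)).estimate == \
        pytest.approx(0.92)
    assert sensitivity(ConfusionMatrix(55, 8, 0, 0)).estimate == \
        pytest.approx(55 / 63)  # 87.3%
    assert sensitivity(ConfusionMatrix(29, 0, 0, 0)).estimate == 1.0


def test_specificity_and_accuracy():
    cm = ConfusionMatrix(92, 8, 1, 193)
    assert specificity(cm).estimate == pytest.approx(193 / 194)
    assert accuracy(cm).estimate == pytest.approx(285 / 294)


def test_zero_denominator_raises():
    with pytest.raises(ValueError, match="denominator"):
        sensitivity(ConfusionMatrix(0, 0, 5, 5))


def test_percent_rendering_half_up():
    m = sensitivity(ConfusionMatrix(92, 8, 0, 0))
    assert m.percent == "92% (85-96%)"


# --------------------------------------------------------- Clopper-Pearson

def _cp_bisect(x, n, conf=0.95, tol=1e-12):
    """Independent oracle: invert the binomial tail tests by bisection."""
    alpha = 1 - conf

    def upper_tail(p):  # P(X >= x)
        return stats.binom.sf(x - 1, n, p)

    def lower_tail(p):  # P(X <= x)
        return stats.binom.cdf(x, n, p)

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    low = 0.0 if x == 0 else bisect(upper_tail, alpha / 2, 0.0, 1.0)
    high = 1.0 if x == n else 1 - bisect(
        lambda p: lower_tail(1 - p), alpha / 2, 0.0, 1.0)
    return low, high


@pytest.mark.parametrize("x,n", [(8, 8), (29, 29), (92, 100), (55, 63),
                                 (0, 10), (3, 17), (45, 60)])
def test_clopper_pearson_matches_bisection_oracle(x, n):
    lo, hi = clopper_pearson(x, n)
    olo, ohi = _cp_bisect(x, n)
    assert lo == pytest.approx(olo, abs=1e-9)
    assert hi == pytest.approx(ohi, abs=1e-9)


def test_clopper_pearson_closed_forms():
    # x = n: low = (alpha/2)^(1/n); x = 0 mirrors it
    for n in (8, 29, 73):
        lo, hi = clopper_pearson(n, n)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / n), abs=1e-10)
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0
    assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-10)


def test_clopper_pearson_invalid():
    with pytest.raises(ValueError):
        clopper_pearson(5, 4)
    with pytest.raises(ValueError):
        clopper_pearson(0, 0)


def test_interval_nesting_99_contains_95():
    """Wider confidence always widens the exact interval: sweep n <= 200."""
    for n in range(1, 201):
        x = np.arange(n + 1)
        lo95 = np.where(x == 0, 0.0, stats.beta.ppf(0.025, x, n - x + 1))
        hi95 = np.where(x == n, 1.0, stats.beta.ppf(0.975, x + 1,
                                                    np.maximum(n - x, 1)))
        lo99 = np.where(x == 0, 0.0, stats.beta.ppf(0.005, x, n - x + 1))
        hi99 = np.where(x == n, 1.0, stats.beta.ppf(0.995, x + 1,
                                                    np.maximum(n - x, 1)))
        assert (lo99 <= lo95 + 1e-12).all() and (hi99 >= hi95 - 1e-12).all()
    # spot-check the vectorized sweep against the public function
    assert clopper_pearson(20, 200, 0.99)[0] == pytest.approx(
        float(stats.beta.ppf(0.005, 20, 181)))


def test_coverage_of_exact_interval():
    """Exact intervals are conservative: simulated coverage >= nominal."""
    rng = np.random.default_rng(42)
    n, p = 60, 0.9
    draws = rng.binomial(n, p, 2000)
    bounds = {x: clopper_pearson(x, n) for x in np.unique(draws)}
    covered = sum(bounds[x][0] <= p <= bounds[x][1] for x in draws)
    assert covered / 2000 >= 0.95


# ------------------------------------------------------------------- AUC

def test_auc_perfect_separation():
    m = roc_auc([1, 2, 9, 10], ["pMMR", "pMMR", "dMMR", "dMMR"], seed=0)
    assert m.estimate == 1.0 and m.ci_high == 1.0


def test_auc_pair_count_example():
    m = roc_auc([1, 3, 2, 4], ["pMMR", "pMMR", "dMMR", "dMMR"], seed=0)
    assert m.estimate == pytest.approx(0.75)


def test_auc_antisymmetry():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=30)
    labels = ["dMMR" if v else "pMMR" for v in rng.random(30) < 0.4]
    a = roc_auc(scores, labels, seed=0).estimate
    b = roc_auc(-scores, labels, seed=0).estimate
    assert a + b == pytest.approx(1.0)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(2)
    scores = rng.choice([0.0, 0.5, 1.0, 1.5], 50)
    y = rng.random(50) < 0.5
    y[0], y[1] = True, False
    labels = ["dMMR" if v else "pMMR" for v in y]
    ours = mann_whitney_auc(scores[y], scores[~y])
    assert ours == pytest.approx(roc_auc_score(y, scores))


def test_auc_delong_ci_brackets_estimate():
    rng = np.random.default_rng(3)
    scores = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)]
    labels = ["pMMR"] * 40 + ["dMMR"] * 40
    boot = roc_auc(scores, labels, seed=5)
    delong = roc_auc(scores, labels, ci_method="delong")
    assert boot.ci_low <= boot.estimate <= boot.ci_high
    assert delong.ci_low <= delong.estimate <= delong.ci_high
    assert delong.estimate == pytest.approx(boot.estimate)
    # the two interval constructions agree to first order
    assert abs(delong.ci_low - boot.ci_low) < 0.08


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1, 2], ["dMMR", "dMMR"])


# ---------------------------------------------------------- group compare

def test_identical_groups_f_zero():
    g = {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}
    res = compare_groups(g)
    assert res.f_statistic == 0.0 and res.p_value == 1.0


def test_anova_hand_worked_sums_of_squares():
    """Three integer groups, n=5 each, F computed by hand.

    Group means 4, 6, 11; grand mean 7; SSB = 5*(9+1+16) = 130;
    SSW = 10+10+10 = 30; F = (130/2) / (30/12) = 26.
    """
    g = {"A": [2, 3, 4, 5, 6], "B": [4, 5, 6, 7, 8],
         "C": [9, 10, 11, 12, 13]}
    g = {k: np.array(v, float) for k, v in g.items()}
    res = compare_groups(g)
    assert res.f_statistic == pytest.approx(26.0)
    assert res.df_between == 2 and res.df_within == 12
    ref = stats.f_oneway(*g.values())
    assert res.f_statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


def test_tukey_matches_scipy():
    rng = np.random.default_rng(4)
    g = {"A": rng.normal(0, 1, 12), "B": rng.normal(0.8, 1, 15),
         "C": rng.normal(2, 1, 10)}
    res = compare_groups(g)
    ref = stats.tukey_hsd(g["A"], g["B"], g["C"])
    for _, row in res.tukey.iterrows():
        i = ["A", "B", "C"].index(row.group_a)
        j = ["A", "B", "C"].index(row.group_b)
        assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-9)


def test_group_mean_cis_contain_means():
    rng = np.random.default_rng(5)
    g = {"A": rng.normal(10, 2, 30), "B": rng.normal(12, 2, 30)}
    res = compare_groups(g)
    for name, row in res.group_stats.iterrows():
        assert row.ci_low <= row["mean"] <= row.ci_high


def test_compare_groups_validation():
    with pytest.raises(ValueError):
        compare_groups({"A": [1, 2, 3]})
    with pytest.raises(ValueError):
        compare_groups({"A": [1, 2], "B": [3]})


# ------------------------------------------------------- purity correlation

def test_purity_correlation_extremes():
    purity = np.array([10, 20, 30, 40, 50.0])
    rho, _ = purity_score_correlation(purity, purity * 0.3)
    assert rho == pytest.approx(1.0)
    rho, _ = purity_score_correlation(purity, -purity)
    assert rho == pytest.approx(-1.0)


def test_purity_correlation_brute_force_ranks():
    purity = np.array([35, 80, 50, 20, 65.0])
    score = np.array([12.0, 15.0, 9.0, 18.0, 11.0])
    rho, _ = purity_score_correlation(purity, score)
    rp = stats.rankdata(purity)
    rs = stats.rankdata(score)
    d2 = ((rp - rs) ** 2).sum()
    assert rho == pytest.approx(1 - 6 * d2 / (5 * 24))


def test_purity_correlation_needs_three():
    with pytest.raises(ValueError):
        purity_score_correlation([1, 2], [3, 4])
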