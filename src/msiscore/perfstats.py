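"""Diagnostic-performance statistics against the reference MMR labels.

dMMR is the positive class and an MSI-H call the positive prediction
throughout.  Binomial proportions get exact (Clopper-Pearson) intervals;
ROC AUC is the Mann-Whitney statistic with ties counted one half, with a
stratified-bootstrap (or DeLong) confidence interval; group comparisons of
MSI degree use one-way ANOVA with Tukey HSD via the studentized-range
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricWithCI",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "clopper_pearson",
    "mann_whitney_auc",
    "roc_auc",
    "GroupComparison",
    "compare_groups",
    "purity_score_correlation",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """dMMR = positive class; MSI-H call = positive prediction."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    method: str = ""
    n: int = 0

    @property
    def percent(self) -> str:
        """Half-up integer-percent rendering, e.g. '92% (85-96%)'."""
        def pct(x: float) -> int:
            return int(np.floor(x * 100 + 0.5))
        return (f"{pct(self.estimate)}% "
                f"({pct(self.ci_low)}-{pct(self.ci_high)}%)")


def confusion(predicted: Sequence[str], labels: Sequence[str]
              ) -> ConfusionMatrix:
    """Cross-tabulate MSI-H/MSS predictions against dMMR/pMMR labels.

    FAILED predictions must be excluded upstream.
    """
    if len(predicted) != len(labels):
        raise ValueError("predicted and labels differ in length")
    tp = fn = fp = tn = 0
    for pred, lab in zip(predicted, labels):
        if pred == "FAILED":
            raise ValueError("FAILED status passed to confusion()")
        pos_pred = pred == "MSI-H"
        pos_lab = lab == "dMMR"
        if pos_lab:
            tp += pos_pred
            fn += not pos_pred
        else:
            fp += pos_pred
            tn += not pos_pred
    return ConfusionMatrix(tp, fn, fp, tn)


def clopper_pearson(x: int, n: int, conf_level: float = 0.95
                    ) -> tuple[float, float]:
    """Exact two-sided binomial interval by inverting the tail tests.

    The bounds are the standard beta quantiles; the degenerate ends satisfy
    the closed forms low = (alpha/2)**(1/n) when x = n and
    high = 1 - (alpha/2)**(1/n) when x = 0.
    """
    if n <= 0 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n > 0, got x={x}, n={n}")
    alpha = 1.0 - conf_level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _proportion_metric(x: int, n: int, conf_level: float, name: str
                       ) -> MetricWithCI:
    if n == 0:
        raise ValueError(f"{name} undefined: zero denominator")
    low, high = clopper_pearson(x, n, conf_level)
    return MetricWithCI(x / n, low, high, conf_level,
                        method=f"{name}/clopper-pearson", n=n)


def sensitivity(cm: ConfusionMatrix, conf_level: float = 0.95) -> MetricWithCI:
    return _proportion_metric(cm.tp, cm.tp + cm.fn, conf_level, "sensitivity")


def specificity(cm: ConfusionMatrix, conf_level: float = 0.95) -> MetricWithCI:
    return _proportion_metric(cm.tn, cm.tn + cm.fp, conf_level, "specificity")


def accuracy(cm: ConfusionMatrix, conf_level: float = 0.95) -> MetricWithCI:
    return _proportion_metric(cm.tp + cm.tn, cm.n, conf_level, "accuracy")


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability that a random positive outranks
    a random negative, ties counted 1/2."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2)
                 / (pos.size * neg.size))


def _delong_ci(pos, neg, conf_level):
    """DeLong variance of the Mann-Whitney AUC (placement values)."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
                    for q in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + conf_level / 2)
    half = z * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def roc_auc(scores: Sequence[float], labels: Sequence, positive="dMMR",
            ci_method: str = "bootstrap", n_boot: int = 2000,
            seed: int = 0, conf_level: float = 0.95) -> MetricWithCI:
    """Mann-Whitney AUC with a stratified bootstrap-percentile CI.

    ``ci_method="delong"`` switches to the asymptotic DeLong interval.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray([lab == positive for lab in labels])
    pos, neg = scores[mask], scores[~mask]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    auc = mann_whitney_auc(pos, neg)
    if ci_method == "delong":
        auc, low, high = _delong_ci(pos, neg, conf_level)
        return MetricWithCI(auc, low, high, conf_level, "auc/delong",
                            n=pos.size + neg.size)
    if ci_method != "bootstrap":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        boots[b] = mann_whitney_auc(bp, bn)
    alpha = 1 - conf_level
    low, high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return MetricWithCI(auc, float(low), float(high), conf_level,
                        f"auc/bootstrap({n_boot})", n=pos.size + neg.size)


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_stats: pd.DataFrame       # n, mean, ci_low, ci_high per group
    tukey: pd.DataFrame             # group_a, group_b, mean_diff, p_adj


def compare_groups(groups: Mapping[str, Sequence[float]],
                   conf_level: float = 0.95) -> GroupComparison:
    """One-way ANOVA with all-pairs Tukey HSD.

    F is computed from between/within sums of squares; Tukey adjusted
    p-values come from the studentized-range distribution with the
    Tukey-Kramer allowance for unequal group sizes.  Group means carry
    t-based confidence intervals from the pooled within-group variance.
    """
    names = list(groups)
    data = {g: np.asarray(groups[g], dtype=float) for g in names}
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("every group needs n >= 2")

    all_vals = np.concatenate([data[g] for g in names])
    n_total = all_vals.size
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
    else:
        f_stat = ms_between / ms_within
    p = 1.0 if f_stat == 0 else float(stats.f.sf(f_stat, df_b, df_w))

    tcrit = stats.t.ppf(0.5 + conf_level / 2, df_w)
    rows = []
    for g in names:
        v = data[g]
        half = tcrit * np.sqrt(ms_within / len(v))
        rows.append((g, len(v), v.mean(), v.mean() - half, v.mean() + half))
    group_stats = pd.DataFrame(
        rows, columns=["group", "n", "mean", "ci_low", "ci_high"]
    ).set_index("group")

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            va, vb = data[a], data[b]
            diff = va.mean() - vb.mean()
            se = np.sqrt(ms_within / 2 * (1 / len(va) + 1 / len(vb)))
            if se == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
            pairs.append((a, b, diff, p_adj))
    tukey = pd.DataFrame(pairs,
                         columns=["group_a", "group_b", "mean_diff", "p_adj"])
    return GroupComparison(f_stat, p, df_b, df_w, group_stats, tukey)


def purity_score_correlation(purity: Sequence[float],
                             scores: Sequence[float]
                             ) -> tuple[float, float]:
    """Spearman rank correlation of tumor purity against MSI score.

    Intended for MSI-H samples, where a purity dependence would signal
    dilution-limited scoring.
    """
    purity = np.asarray(purity, dtype=float)
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(purity) & np.isfinite(scores)
    if ok.sum() < 3:
        raise ValueError("need at least 3 samples with purity and score")
    rho, p = stats.spearmanr(purity[ok], scores[ok])
    return float(rho), float(p)
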