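import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from msiscore import (CohortTable, PanelQCConfig, cluster_loci, greedy_select,
                      locus_auc, locus_auc_profiles, locus_differential,
                      normal_baseline_qc, simulate_planted_cohort)
from msiscore.caller import LocusCall
from msiscore.selection import average_linkage, linkage_to_newick


def _cohort(columns: dict, labels, types=None):
    n = len(labels)
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    return CohortTable(
        proportions=pd.DataFrame(columns, index=idx, dtype=float),
        mmr_label=pd.Series(labels, index=idx),
        cancer_type=pd.Series(types if types is not None else "UCEC",
                              index=idx),
    )


# ---------------------------------------------------------------- locus AUC

def test_locus_auc_perfect_separation():
    c = _cohort({"A": [0.01, 0.02, 0.3, 0.4]},
                ["pMMR", "pMMR", "dMMR", "dMMR"])
    assert locus_auc(c, "A") == 1.0


def test_locus_auc_interleaved_pair_count():
    # pMMR {1,3}, dMMR {2,4}: 3 of 4 pairs won => 0.75
    c = _cohort({"A": [0.1, 0.3, 0.2, 0.4]},
                ["pMMR", "pMMR", "dMMR", "dMMR"])
    assert locus_auc(c, "A") == pytest.approx(0.75)


def test_locus_auc_all_ties():
    c = _cohort({"A": [0.2] * 6}, ["pMMR", "dMMR"] * 3)
    assert locus_auc(c, "A") == pytest.approx(0.5)


def test_locus_auc_single_class_is_none():
    c = _cohort({"A": [0.1, 0.2]}, ["dMMR", "dMMR"])
    assert locus_auc(c, "A") is None


def test_locus_auc_matches_exhaustive_pairs():
    rng = np.random.default_rng(11)
    for _ in range(30):
        n_pos, n_neg = rng.integers(2, 11, 2)
        vals = rng.choice([0.0, 0.1, 0.2, 0.3], n_pos + n_neg)
        labels = ["dMMR"] * n_pos + ["pMMR"] * n_neg
        c = _cohort({"A": vals}, labels)
        pos, neg = vals[:n_pos], vals[n_pos:]
        brute = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg) \
            / (n_pos * n_neg)
        assert locus_auc(c, "A") == pytest.approx(brute)


# ------------------------------------------------------------ greedy select

def test_greedy_keeps_informative_drops_noise():
    rng = np.random.default_rng(2)
    n = 60
    labels = ["pMMR"] * 30 + ["dMMR"] * 30
    informative = np.r_[rng.uniform(0, 0.05, 30), rng.uniform(0.4, 0.6, 30)]
    noise = rng.uniform(0, 0.05, n)
    c = _cohort({"INF": informative, "NOISE": noise}, labels)
    res = greedy_select(c, ["INF", "NOISE"], order_by="UCEC")
    assert res.selected == ["INF"]
    assert len(res.auc_trajectory) == 1
    # exhaustive oracle over the three non-empty subsets: INF alone is best
    def subset_auc(cols):
        s = c.proportions[list(cols)].sum(axis=1)
        pos = s[c.is_dmmr].to_numpy()
        neg = s[~c.is_dmmr].to_numpy()
        from msiscore import mann_whitney_auc
        return mann_whitney_auc(pos, neg)
    assert subset_auc(["INF"]) >= max(subset_auc(["NOISE"]),
                                      subset_auc(["INF", "NOISE"]))


def test_greedy_duplicate_column_never_readded():
    rng = np.random.default_rng(3)
    labels = ["pMMR"] * 25 + ["dMMR"] * 25
    a = np.r_[rng.uniform(0, 0.1, 25), rng.uniform(0.2, 0.5, 25)]
    b = rng.uniform(0, 0.08, 50)
    c = _cohort({"A": a, "B": b, "C": a.copy()}, labels)
    res = greedy_select(c, ["A", "B", "C"], order_by="UCEC")
    assert not {"A", "C"} <= set(res.selected)


def test_greedy_identical_columns_selects_one():
    col = np.r_[np.full(10, 0.05), np.full(10, 0.4)]
    labels = ["pMMR"] * 10 + ["dMMR"] * 10
    c = _cohort({f"L{i}": col for i in range(4)}, labels)
    res = greedy_select(c, list(c.locus_ids), order_by="UCEC", tol=0)
    assert len(res.selected) == 1


def test_greedy_trajectory_strictly_increasing():
    cohort, planted = simulate_planted_cohort(seed=4)
    res = greedy_select(cohort, cohort.locus_ids)
    traj = res.auc_trajectory
    assert all(b > a for a, b in zip(traj, traj[1:]))
    assert set(planted) <= set(res.selected)
    assert traj[-1] >= max(
        filter(None, (locus_auc(cohort, l) for l in cohort.locus_ids)))


def test_greedy_degenerate_labels():
    c = _cohort({"A": [0.1, 0.2], "B": [0.3, 0.1]}, ["dMMR", "dMMR"])
    with pytest.raises(ValueError, match="degenerate"):
        greedy_select(c, ["A", "B"])


# -------------------------------------------------------------- clustering

def test_identical_profiles_merge_at_zero():
    prof = pd.DataFrame({"COAD": [0.9, 0.9], "UCEC": [0.7, 0.7]},
                        index=["A", "B"])
    merges = cluster_loci(prof)
    assert merges[0, 2] == 0.0


def test_manual_average_linkage_oracle():
    # abstract dissimilarities d(0,1)=1, d(0,2)=1, d(1,2)=4:
    # ties resolve to the lowest-index pair (0,1); then the merged pair
    # joins 2 at height (1+4)/2 = 2.5
    d = squareform(np.array([[0, 1, 1], [1, 0, 4], [1, 4, 0]], float))
    merges = average_linkage(d)
    assert (merges[0, 0], merges[0, 1], merges[0, 2]) == (0, 1, 1.0)
    assert merges[1, 2] == pytest.approx(2.5)


def test_linkage_matches_scipy_on_random_profiles():
    rng = np.random.default_rng(8)
    mat = rng.uniform(0.4, 1.0, (12, 3))
    ours = average_linkage(pdist(mat))
    scipys = hierarchy.linkage(mat, method="average")
    assert np.allclose(np.sort(ours[:, 2]), np.sort(scipys[:, 2]))


def test_cluster_heights_permutation_invariant():
    rng = np.random.default_rng(9)
    prof = pd.DataFrame(rng.uniform(0.4, 1, (8, 3)),
                        index=[f"L{i}" for i in range(8)],
                        columns=["COAD", "STAD", "UCEC"])
    a = cluster_loci(prof)
    perm = rng.permutation(8)
    b = cluster_loci(prof.iloc[perm])
    assert np.allclose(np.sort(a[:, 2]), np.sort(b[:, 2]))


def test_cluster_requires_two_profiles():
    with pytest.raises(ValueError):
        cluster_loci(pd.DataFrame({"COAD": [0.9]}, index=["A"]))


def test_newick_rendering():
    prof = pd.DataFrame({"COAD": [0.9, 0.9, 0.1]}, index=["A", "B", "C"])
    merges = cluster_loci(prof)
    nwk = linkage_to_newick(merges, ["A", "B", "C"])
    assert nwk.endswith(";") and {"A", "B", "C"} <= set(
        nwk.replace("(", " ").replace(",", " ").replace(":", " ").split())


# ---------------------------------------------------------- normal-tissue QC

def test_normal_qc_decisions():
    calls = {
        "DEAD": [LocusCall("DEAD", 0, 0, None, False)] * 3,
        "NOISY": [LocusCall("NOISY", 600, 300, 0.5, True)] * 3,
        "CLEAN": [LocusCall("CLEAN", 600, 30, 0.05, True)] * 3,
    }
    qc = normal_baseline_qc(calls, PanelQCConfig(max_normal_proportion=0.3))
    assert not qc.loc["DEAD", "keep"]
    assert qc.loc["DEAD", "reason"] == "failed_amplification"
    assert not qc.loc["NOISY", "keep"]
    assert qc.loc["NOISY", "reason"] == "high_variability"
    assert qc.loc["CLEAN", "keep"]


def test_normal_qc_mean_proportion_threshold():
    calls = {"B": [LocusCall("B", 600, 360, 0.6, True),
                   LocusCall("B", 600, 240, 0.4, True)]}
    qc = normal_baseline_qc(calls)
    assert qc.loc["B", "mean_proportion"] == pytest.approx(0.5)
    assert qc.loc["B", "reason"] == "high_variability"


# ------------------------------------------------------- differential tests

def test_differential_identical_distributions():
    rng = np.random.default_rng(12)
    v = rng.uniform(0, 0.1, 20)
    # both classes carry the same multiset of values per locus
    col = np.repeat(v, 2)
    c = _cohort({"A": col, "B": col[::-1]}, ["pMMR", "dMMR"] * 20)
    res = locus_differential(c)
    assert (res["p_adjusted"] > 0.9).all()


def test_differential_complete_separation_matches_enumeration():
    vals = np.r_[np.arange(5) * 0.01, 0.2 + np.arange(5) * 0.01]
    labels = ["pMMR"] * 5 + ["dMMR"] * 5
    c = _cohort({"A": vals}, labels)
    res = locus_differential(c)
    ref = mannwhitneyu(vals[5:], vals[:5], alternative="two-sided")
    assert res.loc["A", "statistic"] == pytest.approx(ref.statistic)
    # complete separation of 5 vs 5: exact two-sided p = 2 / C(10,5)
    assert res.loc["A", "p_value"] == pytest.approx(2 / 252)


def test_differential_bh_step_up_by_hand():
    """Adjusted p-values equal the step-up formula applied by hand:
    adj_(i) = min_{j >= i} p_(j) * m / j (so 0.01,0.02,0.03,0.04 -> all
    0.04)."""
    rng = np.random.default_rng(13)
    labels = ["pMMR"] * 12 + ["dMMR"] * 12
    cols = {}
    for i, shift in enumerate([0.0, 0.02, 0.05, 0.2]):
        cols[f"L{i}"] = np.r_[rng.uniform(0, 0.1, 12),
                              rng.uniform(0, 0.1, 12) + shift]
    res = locus_differential(_cohort(cols, labels))
    p = res["p_value"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    by_hand = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        by_hand[i] = running
    assert np.allclose(res["p_adjusted"].to_numpy(), by_hand)


def test_differential_untestable_flagged():
    c = _cohort({"A": [0.1, 0.2, np.nan, np.nan]},
                ["pMMR", "pMMR", "dMMR", "dMMR"])
    res = locus_differential(c)
    assert bool(res.loc["A", "untestable"])


def test_auc_profiles_shape(default_cohort):
    cohort, _ = default_cohort
    prof = locus_auc_profiles(cohort)
    assert list(prof.columns) == ["COAD", "STAD", "UCEC", "overall"]
    assert prof.notna().all().all()
    assert ((prof >= 0) & (prof <= 1)).all().all()
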