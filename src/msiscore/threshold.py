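"""MSS / MSI-H cutoff determination by stratified k-fold cross-validation.

On each training split the score threshold maximising classification
accuracy against the reference dMMR/pMMR labels is swept on a fixed grid;
equally accurate thresholds form a contiguous interval, whose midpoint is
evaluated on the held-out fold.  The final cutoff is the midpoint of the
intersection of the fold-optimal intervals (their union if the intersection
is empty), rounded to the nearest grid point with ties upward - a
deterministic analog of picking the round number out of an optimal band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CohortTable
from .scoring import ScoringConfig, score_cohort

__all__ = ["CVConfig", "FoldResult", "ThresholdResult",
           "find_best_threshold", "cross_validate_threshold"]


@dataclass(frozen=True)
class CVConfig:
    k: int = 4
    grid_step: float = 0.25
    seed: int = 0
    stratify_by: str = "label+type"   # "label" or "label+type"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be positive")
        if self.stratify_by not in ("label", "label+type"):
            raise ValueError("stratify_by must be 'label' or 'label+type'")


@dataclass
class FoldResult:
    fold: int
    interval: tuple[float, float]
    train_accuracy: float
    test_accuracy: float
    n_test: int


@dataclass
class ThresholdResult:
    chosen_cutoff: float
    optimal_interval: tuple[float, float]
    per_fold: list[FoldResult]
    overall_cv_accuracy: float


def _grid_accuracy(scores: np.ndarray, positive: np.ndarray,
                   grid: np.ndarray) -> np.ndarray:
    pred = scores[None, :] >= grid[:, None]
    return (pred == positive[None, :]).mean(axis=1)


def find_best_threshold(scores: Sequence[float], labels: Sequence,
                        grid_step: float = 0.25, positive="dMMR"
                        ) -> tuple[tuple[float, float], float]:
    """Sweep thresholds on a grid and return the maximal-accuracy interval.

    accuracy(t) = fraction of samples with (score >= t) == (label == dMMR).
    Among equally accurate grid runs the longest is returned (the rightmost
    on length ties).  Returns ((lo, hi), accuracy).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray([lab == positive for lab in labels])
    if positive.all() or not positive.any():
        raise ValueError("degenerate labels: only one class present")
    lo = scores.min() - grid_step
    hi = scores.max() + grid_step
    n_steps = int(np.ceil((hi - lo) / grid_step)) + 1
    grid = lo + grid_step * np.arange(n_steps)
    acc = _grid_accuracy(scores, positive, grid)
    best = acc.max()
    at_best = np.isclose(acc, best)
    # contiguous runs of best-accuracy grid points
    runs = []
    start = None
    for i, flag in enumerate(at_best):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(grid) - 1))
    s, e = max(runs, key=lambda r: (r[1] - r[0], r[1]))
    return (float(grid[s]), float(grid[e])), float(best)


def _stratified_folds(strata: list, k: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Fold id per sample: shuffle within stratum, deal round-robin.

    Strata smaller than k are merged into one pooled stratum (warned).
    """
    strata = np.asarray(strata, dtype=object)
    counts = {s: int((strata == s).sum()) for s in set(strata.tolist())}
    small = sorted(str(s) for s, c in counts.items() if c < k)
    if small:
        warnings.warn(
            f"strata smaller than k={k} merged: {small}", stacklevel=3
        )
    keys = np.array(
        ["__merged__" if counts[s] < k else str(s) for s in strata.tolist()]
    )
    folds = np.empty(len(strata), dtype=int)
    offset = 0
    for key in sorted(set(keys.tolist())):
        idx = np.flatnonzero(keys == key)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[i] = (pos + offset) % k
        offset += len(idx)   # stagger so small strata spread over folds
    return folds


def cross_validate_threshold(cohort: CohortTable,
                             panel_or_ids,
                             scoring_config: ScoringConfig | None = None,
                             cv_config: CVConfig | None = None
                             ) -> ThresholdResult:
    """k-fold stratified CV of the score cutoff on a labelled cohort."""
    scoring_config = scoring_config or ScoringConfig()
    cv = cv_config or CVConfig()
    labelled = cohort.mmr_label.isin(["dMMR", "pMMR"])
    cohort = cohort.subset_samples(labelled)
    n = len(cohort)
    if cv.k > n:
        raise ValueError(f"k={cv.k} exceeds cohort size {n}")

    scored = score_cohort(cohort, panel_or_ids, scoring_config)
    ok = scored["status"] != "FAILED"
    scores = scored.loc[ok, "msi_score"].to_numpy()
    labels = cohort.mmr_label.loc[ok].to_numpy()

    if cv.stratify_by == "label":
        strata = list(labels)
    else:
        strata = [f"{l}|{t}" for l, t in
                  zip(labels, cohort.cancer_type.loc[ok])]

    rng = np.random.default_rng(cv.seed)
    folds = _stratified_folds(strata, cv.k, rng)

    per_fold: list[FoldResult] = []
    correct = 0
    for f in range(cv.k):
        test = folds == f
        train = ~test
        (lo, hi), train_acc = find_best_threshold(
            scores[train], labels[train], cv.grid_step)
        mid = (lo + hi) / 2
        pred_pos = scores[test] >= mid
        is_pos = labels[test] == "dMMR"
        n_correct = int((pred_pos == is_pos).sum())
        correct += n_correct
        per_fold.append(FoldResult(f, (lo, hi), train_acc,
                                   n_correct / test.sum(), int(test.sum())))

    los = [fr.interval[0] for fr in per_fold]
    his = [fr.interval[1] for fr in per_fold]
    lo, hi = max(los), min(his)
    if lo > hi:                      # empty intersection -> union
        lo, hi = min(los), max(his)
    mid = (lo + hi) / 2
    # round to nearest grid point, ties upward
    step = cv.grid_step
    chosen = float(np.floor(mid / step + 0.5) * step)

    return ThresholdResult(
        chosen_cutoff=chosen,
        optimal_interval=(lo, hi),
        per_fold=per_fold,
        overall_cv_accuracy=correct / len(scores),
    )
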