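"""Locus-panel optimization: per-locus AUC, normal-tissue QC, clustering,
differential variability and greedy forward selection.

The greedy procedure mirrors the panel-reduction idea: rank loci by their
individual AUC for the ordering cancer type (endometrial by default, the
hardest type), then walk the ranking, keeping a locus only when adding its
proportion to the running score sum strictly improves the overall AUC
against the dMMR/pMMR labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .caller import LocusCall
from .cohort import CohortTable
from .panel import PanelDefinition
from .perfstats import mann_whitney_auc

__all__ = [
    "PanelQCConfig",
    "SelectionResult",
    "locus_auc",
    "locus_auc_profiles",
    "greedy_select",
    "cluster_loci",
    "average_linkage",
    "linkage_to_newick",
    "normal_baseline_qc",
    "locus_differential",
]


@dataclass(frozen=True)
class PanelQCConfig:
    """Normal-tissue baseline exclusion rules.

    A locus is dropped when amplification fails (mean depth below
    ``min_normal_depth``) or when its background variant proportion in
    normal samples exceeds ``max_normal_proportion`` - a stutter level that
    would drown somatic signal.
    """

    max_normal_proportion: float = 0.30
    min_normal_depth: int = 50

    def __post_init__(self):
        if not 0 < self.max_normal_proportion < 1:
            raise ValueError("max_normal_proportion must be in (0, 1)")


@dataclass
class SelectionResult:
    ordering_used: list[str]
    selected: list[str]
    auc_trajectory: list[float]


def locus_auc(cohort: CohortTable, locus_id: str,
              cancer_type: str | None = None) -> float | None:
    """Mann-Whitney AUC of one locus's proportion for dMMR vs pMMR.

    ``cancer_type=None`` uses the whole labelled cohort.  Returns None when
    the (filtered) subset contains a single class.
    """
    mask = cohort.mmr_label.isin(["dMMR", "pMMR"])
    if cancer_type is not None:
        mask &= cohort.cancer_type == cancer_type
    vals = cohort.proportions.loc[mask, locus_id].to_numpy(dtype=float)
    pos = cohort.mmr_label.loc[mask].to_numpy() == "dMMR"
    ok = np.isfinite(vals)
    vals, pos = vals[ok], pos[ok]
    if pos.all() or not pos.any():
        return None
    return mann_whitney_auc(vals[pos], vals[~pos])


def locus_auc_profiles(cohort: CohortTable,
                       cancer_types: Sequence[str] | None = None
                       ) -> pd.DataFrame:
    """AUC per locus per cancer type plus 'overall'; loci as rows."""
    if cancer_types is None:
        cancer_types = sorted(cohort.cancer_type.dropna().unique())
    cols = {}
    for ct in list(cancer_types) + [None]:
        name = ct if ct is not None else "overall"
        cols[name] = [locus_auc(cohort, l, ct) for l in cohort.locus_ids]
    return pd.DataFrame(cols, index=cohort.locus_ids, dtype=float)


def greedy_select(cohort: CohortTable,
                  panel: PanelDefinition | Sequence[str],
                  order_by: str = "UCEC",
                  tol: float = 1e-6) -> SelectionResult:
    """Greedy forward selection of loci by cumulative-score AUC.

    Loci are visited in descending ``order_by``-type AUC (ties broken by
    locus_id ascending); a locus is kept iff the overall AUC of the running
    proportion sum strictly increases by more than ``tol``.
    """
    locus_ids = (panel.locus_ids if isinstance(panel, PanelDefinition)
                 else list(panel))
    if len(locus_ids) < 2:
        raise ValueError("need at least 2 candidate loci")
    labelled = cohort.mmr_label.isin(["dMMR", "pMMR"])
    sub = cohort.subset_samples(labelled)
    pos = sub.is_dmmr.to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("degenerate labels: only one class present")

    order_auc = {}
    for lid in locus_ids:
        a = locus_auc(sub, lid, order_by)
        if a is None:
            warnings.warn(
                f"locus {lid}: AUC undefined for type {order_by!r}; "
                "placed last in the ordering")
            a = -np.inf
        order_auc[lid] = a
    ordering = sorted(locus_ids, key=lambda l: (-order_auc[l], l))

    mat = sub.proportions[locus_ids].to_numpy(dtype=float)
    col = {lid: i for i, lid in enumerate(locus_ids)}
    running = np.zeros(len(sub))
    current = 0.0
    selected: list[str] = []
    trajectory: list[float] = []
    for lid in ordering:
        tentative = running + np.nan_to_num(mat[:, col[lid]])
        auc = mann_whitney_auc(tentative[pos], tentative[~pos])
        if auc > current + tol:
            running = tentative
            current = auc
            selected.append(lid)
            trajectory.append(auc)
    return SelectionResult(ordering, selected, trajectory)


def average_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerative average-linkage clustering of a condensed or square
    distance matrix; returns a scipy-style (n-1) x 4 linkage array.

    Deterministic: on distance ties the pair with the lowest cluster
    indices merges first.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim == 1:
        d = squareform(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    d = d.copy()
    active = {i: (i, 1) for i in range(n)}     # slot -> (cluster id, size)
    merges = np.zeros((n - 1, 4))
    next_id = n
    slots = list(range(n))
    for step in range(n - 1):
        best = None
        for ii in range(len(slots)):
            for jj in range(ii + 1, len(slots)):
                a, b = slots[ii], slots[jj]
                key = (d[a, b], active[a][0], active[b][0])
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ida, na = active[a]
        idb, nb = active[b]
        merges[step] = (min(ida, idb), max(ida, idb), d[a, b], na + nb)
        # average-linkage update into slot a
        for c in slots:
            if c not in (a, b):
                d[a, c] = d[c, a] = (na * d[a, c] + nb * d[b, c]) / (na + nb)
        active[a] = (next_id, na + nb)
        next_id += 1
        slots.remove(b)
        del active[b]
    return merges


def cluster_loci(profiles: pd.DataFrame) -> np.ndarray:
    """Average-linkage dendrogram of loci by Euclidean distance between
    their per-type AUC vectors.

    ``profiles``: loci x cancer-type AUC frame (see
    :func:`locus_auc_profiles`).  Missing AUCs are imputed at 0.5 (the
    uninformative value) with a warning.  Returns a scipy-style linkage
    array; row indices follow the input row order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 locus profiles")
    mat = profiles.to_numpy(dtype=float)
    if np.isnan(mat).any():
        warnings.warn("missing AUC values imputed at 0.5")
        mat = np.where(np.isnan(mat), 0.5, mat)
    return average_linkage(pdist(mat, metric="euclidean"))


def linkage_to_newick(merges: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage array as a Newick string (heights as branch
    lengths, simple nested format)."""
    n = len(labels)
    node: dict[int, tuple[str, float]] = {
        i: (str(labels[i]), 0.0) for i in range(n)
    }
    for step, (a, b, height, _) in enumerate(merges):
        sa, ha = node[int(a)]
        sb, hb = node[int(b)]
        h = float(height) / 2
        node[n + step] = (
            f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})", h
        )
    return node[n + len(merges) - 1][0] + ";"


def normal_baseline_qc(normal_calls: Mapping[str, Sequence[LocusCall]],
                       qc: PanelQCConfig | None = None) -> pd.DataFrame:
    """Keep/drop decision per locus from normal-tissue (e.g. leukocyte DNA)
    calls.

    ``normal_calls`` maps locus_id to that locus's calls across the normal
    samples.  Returns a frame with mean_depth, mean_proportion, keep and
    reason columns.
    """
    qc = qc or PanelQCConfig()
    rows = []
    for locus_id, calls in normal_calls.items():
        if not calls:
            raise ValueError(f"{locus_id}: no normal calls supplied")
        mean_depth = float(np.mean([c.depth for c in calls]))
        props = [c.proportion for c in calls if c.proportion is not None]
        mean_prop = float(np.mean(props)) if props else float("nan")
        if mean_depth < qc.min_normal_depth:
            keep, reason = False, "failed_amplification"
        elif not props or mean_prop > qc.max_normal_proportion:
            keep, reason = (False, "high_variability") if props else \
                           (False, "failed_amplification")
        else:
            keep, reason = True, ""
        rows.append((locus_id, mean_depth, mean_prop, keep, reason))
    return pd.DataFrame(
        rows,
        columns=["locus_id", "mean_depth", "mean_proportion", "keep",
                 "reason"],
    ).set_index("locus_id")


def locus_differential(cohort: CohortTable, cancer_type: str | None = None
                       ) -> pd.DataFrame:
    """Per-locus two-sided rank-sum test of dMMR vs pMMR proportions,
    Benjamini-Hochberg adjusted across loci within the type subset."""
    mask = cohort.mmr_label.isin(["dMMR", "pMMR"])
    if cancer_type is not None:
        mask &= cohort.cancer_type == cancer_type
    sub = cohort.subset_samples(mask)
    pos = sub.is_dmmr.to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("degenerate subset: only one class present")

    rows = []
    for lid in sub.locus_ids:
        vals = sub.proportions[lid].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        x, y = vals[ok & pos], vals[ok & ~pos]
        if x.size == 0 or y.size == 0:
            rows.append((lid, np.nan, np.nan, True))
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append((lid, float(res.statistic), float(res.pvalue), False))
    df = pd.DataFrame(rows, columns=["locus_id", "statistic", "p_value",
                                     "untestable"]).set_index("locus_id")
    testable = ~df["untestable"]
    adj = np.full(len(df), np.nan)
    if testable.any():
        adj[testable.to_numpy()] = stats.false_discovery_control(
            df.loc[testable, "p_value"].to_numpy(), method="bh")
    df["p_adjusted"] = adj
    return df
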