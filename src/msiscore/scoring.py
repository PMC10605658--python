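"""MSI score computation and MSS / MSI-H classification.

The MSI score of a sample is S = sum over panel loci of p_i, where p_i is
the fraction of that locus's reads whose repeat length differs from the
reference.  On an n-locus panel S lives in [0, n]; with the 81-locus
configuration the decision cutoff is 10 (inclusive on the MSI-H side), and 4
for the reduced 27-locus configuration.

When some loci fail depth QC the remaining sum is optionally rescaled by
n_total / n_used so a single cutoff stays comparable across samples with
amplicon dropout; a sample with too few usable loci is FAILED outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import LocusCall
from .cohort import CohortTable
from .panel import PanelDefinition

__all__ = ["ScoringConfig", "SampleScore", "compute_msi_score", "classify",
           "score_cohort"]

MSI_H = "MSI-H"
MSS = "MSS"
FAILED = "FAILED"


@dataclass(frozen=True)
class ScoringConfig:
    cutoff: float = 10.0
    rescale_missing: bool = True
    min_loci_fraction: float = 0.8

    def __post_init__(self):
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.min_loci_fraction <= 1:
            raise ValueError("min_loci_fraction must be in (0, 1]")


#: 27-locus configuration: same scoring rule, lower cutoff.
SCORING_27 = ScoringConfig(cutoff=4.0)


@dataclass
class SampleScore:
    sample_id: str
    msi_score: float
    n_loci_used: int
    n_loci_total: int
    status: str
    per_locus: dict[str, float] = field(default_factory=dict)


def classify(score: float, config: ScoringConfig) -> str:
    """MSI-H iff score >= cutoff (the cutoff itself is MSI-H)."""
    if not np.isfinite(score) or score < 0:
        raise ValueError(f"score must be finite and >= 0, got {score}")
    return MSI_H if score >= config.cutoff else MSS


def compute_msi_score(calls: Sequence[LocusCall], panel: PanelDefinition,
                      config: ScoringConfig | None = None,
                      sample_id: str = "sample") -> SampleScore:
    """Sum QC-passed per-locus proportions into the sample's MSI score."""
    config = config or ScoringConfig()
    panel_ids = set(panel.locus_ids)
    unknown = [c.locus_id for c in calls if c.locus_id not in panel_ids]
    if unknown:
        raise ValueError(f"calls reference loci not in panel: {unknown}")

    per_locus = {}
    raw = 0.0
    used = 0
    for call in calls:
        if call.qc_pass and call.proportion is not None:
            per_locus[call.locus_id] = call.proportion
            raw += call.proportion
            used += 1
    total = len(panel)

    if used < config.min_loci_fraction * total:
        return SampleScore(sample_id, float("nan"), used, total, FAILED,
                           per_locus)
    score = raw
    if config.rescale_missing and used < total:
        score = raw * total / used
    return SampleScore(sample_id, score, used, total,
                       classify(score, config), per_locus)


def score_cohort(cohort: CohortTable,
                 panel: PanelDefinition | Sequence[str],
                 config: ScoringConfig | None = None) -> pd.DataFrame:
    """Score every cohort sample on a panel (or locus-id subset).

    NaN matrix entries count as QC-failed loci for that sample.  Returns a
    DataFrame indexed by sample_id with columns msi_score, n_loci_used,
    n_loci_total, status.
    """
    config = config or ScoringConfig()
    locus_ids = (panel.locus_ids if isinstance(panel, PanelDefinition)
                 else list(panel))
    missing = [l for l in locus_ids if l not in cohort.proportions.columns]
    if missing:
        raise ValueError(f"cohort lacks loci: {missing}")

    mat = cohort.proportions[locus_ids].to_numpy(dtype=float)
    used = np.isfinite(mat).sum(axis=1)
    raw = np.nansum(mat, axis=1)
    total = len(locus_ids)

    score = raw.copy()
    if config.rescale_missing:
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(used > 0, raw * total / np.maximum(used, 1), np.nan)
    failed = used < config.min_loci_fraction * total
    score = np.where(failed, np.nan, score)
    status = np.where(failed, FAILED,
                      np.where(score >= config.cutoff, MSI_H, MSS))
    return pd.DataFrame(
        {
            "msi_score": score,
            "n_loci_used": used,
            "n_loci_total": total,
            "status": status,
        },
        index=cohort.proportions.index,
    )
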