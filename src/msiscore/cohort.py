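"""Cohort container: a samples x loci proportion matrix with clinical labels.

The substrate for cutoff cross-validation, locus selection and performance
statistics.  Proportions are fractions in [0, 1]; NaN marks a locus that
failed QC for that sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "read_cohort", "write_cohort"]

_META_COLUMNS = ("mmr_label", "cancer_type", "tumor_purity")


@dataclass
class CohortTable:
    """Samples x loci variant-proportion matrix plus per-sample metadata.

    Attributes
    ----------
    proportions : DataFrame indexed by sample_id, one column per locus_id.
    mmr_label : Series of reference labels, "dMMR" or "pMMR" (from IHC).
    cancer_type : Series of type codes (COAD, STAD, UCEC, ...).
    tumor_purity : Series of tumor-cell percentages (may hold NaN).
    msi_score : optional cached score per sample.
    """

    proportions: pd.DataFrame
    mmr_label: pd.Series
    cancer_type: pd.Series
    tumor_purity: pd.Series | None = None
    msi_score: pd.Series | None = None

    def __post_init__(self):
        idx = self.proportions.index
        for name in ("mmr_label", "cancer_type", "tumor_purity", "msi_score"):
            s = getattr(self, name)
            if s is not None and not s.index.equals(idx):
                raise ValueError(f"{name} index does not match proportions")
        vals = self.proportions.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("proportions must lie in [0, 1]")
        bad = set(self.mmr_label.dropna()) - {"dMMR", "pMMR"}
        if bad:
            raise ValueError(f"unknown MMR labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.proportions.columns)

    def __len__(self) -> int:
        return len(self.proportions)

    @property
    def is_dmmr(self) -> pd.Series:
        return self.mmr_label == "dMMR"

    def subset_samples(self, mask) -> "CohortTable":
        return CohortTable(
            proportions=self.proportions.loc[mask],
            mmr_label=self.mmr_label.loc[mask],
            cancer_type=self.cancer_type.loc[mask],
            tumor_purity=(None if self.tumor_purity is None
                          else self.tumor_purity.loc[mask]),
            msi_score=(None if self.msi_score is None
                       else self.msi_score.loc[mask]),
        )


def read_cohort(path: str | Path) -> CohortTable:
    """Read the cohort TSV dialect: sample_id, mmr_label, cancer_type,
    tumor_purity, then one column per locus."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks columns: {missing}")
    locus_cols = [c for c in df.columns if c not in _META_COLUMNS]
    return CohortTable(
        proportions=df[locus_cols].astype(float),
        mmr_label=df["mmr_label"],
        cancer_type=df["cancer_type"],
        tumor_purity=pd.to_numeric(df["tumor_purity"], errors="coerce"),
    )


def write_cohort(cohort: CohortTable, path: str | Path,
                 header_lines: list[str] | None = None) -> None:
    purity = (cohort.tumor_purity if cohort.tumor_purity is not None
              else pd.Series(np.nan, index=cohort.proportions.index))
    meta = pd.DataFrame(
        {
            "mmr_label": cohort.mmr_label,
            "cancer_type": cohort.cancer_type,
            "tumor_purity": purity,
        }
    )
    out = pd.concat([meta, cohort.proportions], axis=1)
    out.index.name = "sample_id"
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t")
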