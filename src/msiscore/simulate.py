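"""Synthetic cohorts and amplicon reads with known ground truth.

Two generative paths share one parameterisation:

* the cohort path draws per-sample, per-locus variant proportions directly
  (milliseconds; the substrate for cutoff CV, selection and statistics);
* the read path writes FASTQ amplicons locus by locus so the flank-anchored
  caller can be exercised end to end.

The generative model: every locus carries PCR-stutter background (variant
proportion ~ Normal(0.08, 0.03) truncated to [0, 0.3]) in any tissue; in an
MSI-H sample a random fraction of loci additionally gains a cancer-type
effect, linearly diluted by tumor purity.  Effect magnitudes are solved so
that at 80% purity the expected MSI scores hit the group anchors COAD 19.5,
STAD 16.2, UCEC 13.3 on an 81-locus panel, with MSS samples near
81 x 0.08 = 6.5.  Amplicon depth is a gamma-Poisson (negative-binomial)
draw with median ~650; at that median the distribution cannot also reach
the very heavy right quartile seen on real instruments, so the fitted IQR
is [331, 1134].
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .panel import LocusDefinition, PanelDefinition, load_panel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TABLE_DESIGN_294",
    "GROUP_MEAN_ANCHORS",
    "simulate_cohort",
    "simulate_planted_cohort",
    "simulate_sample_reads",
    "mix_purity",
    "draw_depths",
    "synthetic_panel",
    "demo_panel",
    "expected_msi_score",
]

#: Reference-cohort composition: (cancer_type, mmr_label) -> n samples.
TABLE_DESIGN_294: dict[tuple[str, str], int] = {
    ("UCEC", "dMMR"): 63, ("UCEC", "pMMR"): 74,
    ("COAD", "dMMR"): 29, ("COAD", "pMMR"): 47,
    ("STAD", "dMMR"): 8,  ("STAD", "pMMR"): 73,
}

#: Published MSI-H group-mean MSI scores used as calibration anchors.
GROUP_MEAN_ANCHORS = {"COAD": 19.5, "STAD": 16.2, "UCEC": 13.3}

_CALIB_PURITY = 0.8
_CALIB_N_LOCI = 81


def _solve_effects(stutter_mean: float, affected_fraction: Mapping[str, float]
                   ) -> dict[str, float]:
    """Per-type effect so E[score] hits the anchor at calibration purity."""
    base = stutter_mean * _CALIB_N_LOCI
    return {
        ct: (anchor - base)
            / (_CALIB_PURITY * affected_fraction[ct] * _CALIB_N_LOCI)
        for ct, anchor in GROUP_MEAN_ANCHORS.items()
    }


@dataclass
class SimulationConfig:
    """All generative parameters; a fixed seed makes outputs byte-identical."""

    panel: PanelDefinition | None = None
    n_per_group: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(TABLE_DESIGN_294))
    stutter_mean: float = 0.08
    stutter_sd: float = 0.03
    stutter_max: float = 0.30
    stutter_scale_sd: float = 0.15
    affected_fraction_by_type: Mapping[str, float] = field(
        default_factory=lambda: {"COAD": 0.5, "STAD": 0.5, "UCEC": 0.5})
    msi_effect_by_type: Mapping[str, float] | None = None
    severity_sd: float = 0.2
    depth_mean: float = 827.0
    depth_shape: float = 1.48
    purity: float = 0.8
    purity_range: tuple[float, float] | None = None
    error_rate: float = 0.002
    anchor_protect_len: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.msi_effect_by_type is None:
            self.msi_effect_by_type = _solve_effects(
                self.stutter_mean, self.affected_fraction_by_type)
        for name in ("stutter_mean", "stutter_sd", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must be in [0, 1]")
        if self.depth_mean < 1 or self.depth_shape <= 0:
            raise ValueError("invalid depth model parameters")

    def get_panel(self) -> PanelDefinition:
        return self.panel if self.panel is not None else demo_panel()

    def to_json(self) -> str:
        d = asdict(self)
        panel = d.pop("panel")
        d["panel"] = None if panel is None else self.get_panel().panel_name
        d["n_per_group"] = {f"{ct}|{lab}": n
                            for (ct, lab), n in self.n_per_group.items()}
        return json.dumps(d, indent=2, default=str)


@dataclass
class GroundTruth:
    """What the generator actually drew, sample by sample."""

    expected_proportions: pd.DataFrame   # samples x loci, pre-noise p
    status: pd.Series                    # MSI-H / MSS
    cancer_type: pd.Series
    purity: pd.Series                    # fraction of tumor DNA


def draw_depths(n: int, rng: np.random.Generator,
                mean: float = 827.0, shape: float = 1.48) -> np.ndarray:
    """Gamma-Poisson amplicon depths (median ~650 at the defaults)."""
    lam = rng.gamma(shape, mean / shape, size=n)
    return rng.poisson(lam)


def mix_purity(p_tumor: Sequence[float], p_normal: Sequence[float],
               f: float) -> np.ndarray:
    """Proportions of a DNA mixture with tumor fraction ``f``.

    Elementwise f*p_tumor + (1-f)*p_normal, assuming equal amplification
    efficiency of the two DNAs.  Because the MSI score is a sum, the score
    of the mixture is exactly f*S_tumor + (1-f)*S_normal, so a sample
    crosses a cutoff c at tumor fraction f* = (c - S_N) / (S_T - S_N).
    """
    p_tumor = np.asarray(p_tumor, dtype=float)
    p_normal = np.asarray(p_normal, dtype=float)
    if p_tumor.shape != p_normal.shape:
        raise ValueError("proportion vectors differ in shape")
    if not 0 <= f <= 1:
        raise ValueError("tumor fraction must be in [0, 1]")
    return f * p_tumor + (1 - f) * p_normal


def expected_msi_score(config: SimulationConfig, cancer_type: str,
                       status: str = "MSI-H",
                       purity: float | None = None) -> float:
    """Expected score under the generative model (no sampling noise)."""
    n = len(config.get_panel())
    base = config.stutter_mean * n
    if status != "MSI-H":
        return base
    f = config.purity if purity is None else purity
    return base + (f * config.affected_fraction_by_type[cancer_type]
                   * config.msi_effect_by_type[cancer_type] * n)


def _draw_purity(config: SimulationConfig,
                 rng: np.random.Generator) -> float:
    if config.purity_range is None:
        return config.purity
    lo, hi = config.purity_range
    return float(rng.uniform(lo, hi))


def _sample_expected(config: SimulationConfig, cancer_type: str,
                     msi_high: bool, n_loci: int,
                     rng: np.random.Generator,
                     purity: float | None = None) -> np.ndarray:
    # per-sample stutter scale: FFPE specimens differ in overall background,
    # which is what spreads MSS scores over a band rather than a point
    scale = max(0.4, rng.normal(1.0, config.stutter_scale_sd))
    stutter = np.clip(
        scale * rng.normal(config.stutter_mean, config.stutter_sd, n_loci),
        0.0, config.stutter_max)
    if not msi_high:
        return stutter
    f = config.purity if purity is None else purity
    affected = rng.random(n_loci) < \
        config.affected_fraction_by_type[cancer_type]
    severity = max(0.0, rng.normal(1.0, config.severity_sd))
    effect = config.msi_effect_by_type[cancer_type] * severity
    return np.clip(stutter + f * effect * affected, 0.0, 1.0)


def simulate_cohort(config: SimulationConfig | None = None
                    ) -> tuple[CohortTable, GroundTruth]:
    """Draw a labelled cohort of per-locus proportions.

    dMMR samples are generated MSI-H and pMMR samples MSS (the reference
    label and the true state coincide in the generator; discordance in real
    cohorts comes from biology the model does not emulate).  Observed
    proportions are binomial draws at the locus depth around the expected
    proportion; zero-depth loci become NaN.
    """
    config = config or SimulationConfig()
    panel = config.get_panel()
    n_loci = len(panel)
    rng = np.random.default_rng(config.seed)

    rows, expected_rows, ids, labels, types, purities = [], [], [], [], [], []
    for (ct, lab), n in sorted(config.n_per_group.items()):
        msi_high = lab == "dMMR"
        for i in range(n):
            f = _draw_purity(config, rng)
            purities.append(f)
            expected = _sample_expected(config, ct, msi_high, n_loci, rng,
                                        purity=f)
            depth = draw_depths(n_loci, rng, config.depth_mean,
                                config.depth_shape)
            with np.errstate(invalid="ignore"):
                obs = np.where(depth > 0,
                               rng.binomial(depth, expected)
                               / np.maximum(depth, 1),
                               np.nan)
            ids.append(f"{ct}_{lab}_{i:03d}")
            labels.append(lab)
            types.append(ct)
            rows.append(obs)
            expected_rows.append(expected)

    index = pd.Index(ids, name="sample_id")
    locus_ids = panel.locus_ids
    cohort = CohortTable(
        proportions=pd.DataFrame(rows, index=index, columns=locus_ids),
        mmr_label=pd.Series(labels, index=index),
        cancer_type=pd.Series(types, index=index),
        tumor_purity=pd.Series(np.asarray(purities) * 100.0, index=index),
    )
    truth = GroundTruth(
        expected_proportions=pd.DataFrame(expected_rows, index=index,
                                          columns=locus_ids),
        status=pd.Series(
            ["MSI-H" if l == "dMMR" else "MSS" for l in labels], index=index),
        cancer_type=cohort.cancer_type.copy(),
        purity=pd.Series(purities, index=index, dtype=float),
    )
    return cohort, truth


def simulate_planted_cohort(seed: int = 0, n_mss: int = 300,
                            n_msi: int = 300, n_loci: int = 81,
                            n_informative: int = 10, effect: float = 0.7,
                            stutter_range: tuple[float, float] = (0.02, 0.08),
                            pool_fraction: float = 1 / 3,
                            pool_affect_prob: float = 0.9,
                            ) -> tuple[CohortTable, list[str]]:
    """Cohort with a known informative-locus subset, for selection tests.

    Each informative locus carries the instability effect in a block of
    MSI-H samples exclusive to it (plus a shared pool), so every planted
    locus holds evidence no other locus can supply and the full planted set
    separates the classes outright.  Returns (cohort, planted locus ids).
    """
    rng = np.random.default_rng(seed)
    lo, hi = stutter_range
    n_total = n_mss + n_msi
    X = rng.uniform(lo, hi, (n_total, n_loci))
    informative = sorted(rng.choice(n_loci, n_informative, replace=False))

    n_pool = int(n_msi * pool_fraction)
    n_excl = (n_msi - n_pool) // n_informative
    perm = rng.permutation(n_msi)
    pool, rest = perm[:n_pool], perm[n_pool:]
    msi_rows = np.arange(n_mss, n_total)
    for j, loc in enumerate(informative):
        exclusive = rest[j * n_excl:(j + 1) * n_excl]
        shared = pool[rng.random(n_pool) < pool_affect_prob]
        X[msi_rows[np.concatenate([exclusive, shared])], loc] += effect

    locus_ids = [f"L{i:03d}" for i in range(n_loci)]
    ids = pd.Index(
        [f"MSS_{i:03d}" for i in range(n_mss)]
        + [f"MSI_{i:03d}" for i in range(n_msi)],
        name="sample_id")
    labels = ["pMMR"] * n_mss + ["dMMR"] * n_msi
    cohort = CohortTable(
        proportions=pd.DataFrame(np.clip(X, 0, 1), index=ids,
                                 columns=locus_ids),
        mmr_label=pd.Series(labels, index=ids),
        cancer_type=pd.Series("UCEC", index=ids),
        tumor_purity=pd.Series(80.0, index=ids),
    )
    return cohort, [locus_ids[i] for i in informative]


# ---------------------------------------------------------------------------
# read-level simulation

def _variant_lengths(ref_len: int, n: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Lengths of variant reads: deletions favored 3:1 over insertions,
    magnitude geometric with mean 1.5."""
    mag = rng.geometric(2 / 3, size=n)
    sign = np.where(rng.random(n) < 0.75, -1, 1)
    return np.maximum(ref_len + sign * mag, 0)


def simulate_sample_reads(config: SimulationConfig, cancer_type: str,
                          status: str, out_path: str | Path,
                          sample_id: str = "sample",
                          truth_path: str | Path | None = None,
                          shuffle: bool = True,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Write one sample's amplicon reads as FASTQ (.gz honored).

    Per locus the read count is a depth draw, the variant fraction the same
    expected proportion the cohort path would use, and variant tract
    lengths deletion-biased geometric.  Substitution errors are applied
    outside the anchor regions (the ``anchor_protect_len`` flank bases
    adjacent to the tract), so length measurement is perturbed only through
    tract indels, never through anchor loss.

    Returns the per-locus truth table (expected proportion, depth, variant
    reads); optionally writes a read-level sidecar TSV
    (read_id, locus_id, true_length).
    """
    config = config if config is not None else SimulationConfig()
    panel = config.get_panel()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    expected = _sample_expected(config, cancer_type, status == "MSI-H",
                                len(panel), rng)
    k = config.anchor_protect_len

    reads: list[tuple[str, str, str, int]] = []  # id, seq, locus, true len
    truth_rows = []
    serial = 0
    for locus, p in zip(panel.loci, expected):
        depth = int(draw_depths(1, rng, config.depth_mean,
                                config.depth_shape)[0])
        n_var = int(rng.binomial(depth, p)) if depth else 0
        lengths = np.full(depth, locus.ref_repeat_length)
        if n_var:
            lengths[:n_var] = _variant_lengths(locus.ref_repeat_length,
                                               n_var, rng)
        truth_rows.append((locus.locus_id, float(p), depth, n_var))
        left, right, unit = locus.left_flank, locus.right_flank, \
            locus.repeat_unit
        # error-eligible positions = everything outside the two anchors
        seq_cache: dict[int, tuple[str, list[int]]] = {}
        for L in np.unique(lengths):
            L = int(L)
            base_seq = left + unit * L + right
            elig = (list(range(len(left) - k))
                    + list(range(len(left), len(left) + L))
                    + list(range(len(left) + L + k, len(base_seq))))
            seq_cache[L] = (base_seq, elig)
        n_errs = (rng.binomial(
            [len(seq_cache[int(L)][1]) for L in lengths],
            config.error_rate)
            if config.error_rate > 0 and depth else
            np.zeros(depth, dtype=int))
        for L, n_err in zip(lengths, n_errs):
            seq, elig = seq_cache[int(L)]
            if n_err:
                s = list(seq)
                for pos in rng.choice(len(elig), n_err, replace=False):
                    i = elig[pos]
                    alt = "ACGT".replace(s[i], "")
                    s[i] = alt[rng.integers(3)]
                seq = "".join(s)
            reads.append((f"{sample_id}:{serial}", seq, locus.locus_id,
                          int(L)))
            serial += 1

    if shuffle:
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]

    opener = gzip.open if str(out_path).endswith(".gz") else open
    with opener(out_path, "wt") as fh:
        for rid, seq, _, _ in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tlocus_id\ttrue_length\n")
            for rid, _, lid, L in reads:
                fh.write(f"{rid}\t{lid}\t{L}\n")

    return pd.DataFrame(
        truth_rows,
        columns=["locus_id", "expected_proportion", "depth", "n_variant"],
    ).set_index("locus_id")


# ---------------------------------------------------------------------------
# synthetic panel

_NAMED_LOCI: list[tuple[str, str]] = [
    # gene-style marker names; tags mark types the locus is noted
    # informative for
    ("ABCC5", "UCEC"), ("IMPDH1", "UCEC"), ("GSE1", "UCEC"),
    ("JAK1", "UCEC"), ("JPH4", "UCEC"), ("CHD3", "UCEC"),
    ("BMPR2", "COAD"), ("ELAV3", "COAD"), ("GLYR1", "COAD"),
    ("ZNF43", "COAD"), ("XYLT2", "STAD"),
    ("BAT25", ""), ("BAT26", ""), ("NR21", ""), ("NR24", ""), ("MONO27", ""),
    ("ACVR2A", ""), ("TGFBR2", ""), ("ASTE1", ""), ("SETD1B", ""),
    ("RNF43", ""), ("MSH3", ""), ("BAX", ""), ("DOCK3", ""), ("MBD4", ""),
    ("CTCF", ""), ("KMT2B", ""), ("SRSF6", ""), ("CASP5", ""),
    ("TCF7L2", ""), ("SEC31A", ""), ("PRDM2", ""), ("RPL22", ""),
    ("ESRP1", ""), ("LTN1", ""), ("FAM111B", ""), ("SPINK5", ""),
    ("SLC22A9", ""), ("MYH11", ""), ("TMEM60", ""),
]


def synthetic_panel(n_loci: int = 81, seed: int = 202310
                    ) -> PanelDefinition:
    """A deterministic, fully synthetic n-locus mononucleotide panel.

    Marker names are gene-style; flanks are random but constrained so every
    tract is maximal and all anchors are unique.  A stand-in for a
    published panel whose coordinates are not reproduced here.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    names = [n for n, _ in _NAMED_LOCI][:n_loci]
    tags = {n: t for n, t in _NAMED_LOCI}
    while len(names) < n_loci:
        names.append(f"MS{len(names) + 1:03d}")

    used_anchors: set[str] = set()
    loci: list[LocusDefinition] = []
    for name in names:
        unit = bases[rng.choice(4, p=[0.45, 0.05, 0.05, 0.45])]
        ref_len = int(rng.integers(10, 25))
        while True:
            left = "".join(bases[i] for i in rng.integers(0, 4, 15))
            right = "".join(bases[i] for i in rng.integers(0, 4, 15))
            if left[-1] == unit or right[0] == unit:
                continue
            anchors = {left[-10:], right[:10]}
            if len(anchors) == 2 and not anchors & used_anchors:
                used_anchors |= anchors
                break
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(100_000, 200_000_000))
        loci.append(LocusDefinition(
            locus_id=name, chrom=chrom, repeat_start=start,
            repeat_end=start + ref_len, repeat_unit=unit,
            ref_repeat_length=ref_len, left_flank=left, right_flank=right,
            cancer_type_tags=frozenset(
                t for t in tags.get(name, "").split(",") if t),
        ))
    panel = PanelDefinition(loci=loci, panel_name=f"synthetic{n_loci}",
                            version="1")
    panel.validate()
    return panel


def demo_panel() -> PanelDefinition:
    """The packaged 81-locus synthetic demonstration panel."""
    with resources.as_file(
            resources.files("msiscore.data") / "synthetic_panel_81.tsv"
    ) as path:
        return load_panel(path)
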