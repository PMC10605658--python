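# Methods

## The assay and the statistic

Mismatch-repair-deficient (dMMR) tumors accumulate indels in short tandem
repeats — microsatellite instability (MSI). This package implements an
amplicon-NGS version of that assay for mononucleotide repeats
(homopolymers): a panel of loci is PCR-amplified and sequenced, and for each
locus *i* the fraction *p<sub>i</sub>* of reads whose repeat-tract length
differs from the reference length is measured. The MSI score of a sample is

    S = Σ_i p_i ,

the summed variant-allele burden over the panel. On an *n*-locus panel,
S ∈ [0, n]. A sample is called MSI-H when S ≥ c (the cutoff is inclusive),
MSS otherwise; with the 81-locus configuration c = 10, with the reduced
27-locus configuration c = 4. Because PCR stutter produces length-variant
reads even in stable tissue, MSS samples score well above zero (≈ 6.5 on 81
loci at the default stutter level); the classification problem is separating
that stutter baseline from the somatic signal.

## Flank-anchored repeat calling

Reads are assigned to loci without genome alignment. Each locus stores the
flanking sequence adjacent to its tract; the `anchor_len` (default 10)
flank bases nearest the tract form two anchors. A read measures a locus
when both anchors occur in it (left before right, each with at most
`max_anchor_mismatch` = 1 Hamming mismatches, N counting as a mismatch);
the observed repeat length is the number of bases strictly between the two
anchor matches. The reverse complement is tried when the forward
orientation fails. Consequences of this design:

* substitutions inside the tract never change the measured length — only
  indels make a read a length-variant, which is exactly what the score
  counts;
* reads that do not fully span the tract cannot be measured and are
  recorded as `truncated`; reads matching both anchors of two loci are
  `ambiguous`, reads matching nothing `no_anchor`. Failures are recorded
  observations, never exceptions, so `reads_seen = reads_assigned +
  Σ failures` holds exactly in every run report.
* paired-end mates are counted as independent observations (no overlap
  consensus); a fragment sequenced twice therefore contributes two reads.
  This is a simplification, acceptable because the statistic is a
  proportion.

Per-locus depth QC uses `min_depth` = 50: below that the binomial standard
error of *p<sub>i</sub>* exceeds ~0.07 and the locus is excluded. When loci
drop out, the remaining sum is rescaled by `n_total / n_used` (switchable)
so one cutoff remains comparable across samples; a sample with fewer than
80% usable loci is reported FAILED rather than scored.

## Cutoff determination

The cutoff is chosen by stratified k-fold cross-validation (default k = 4,
strata = MMR label × cancer type; strata smaller than k are pooled with a
warning). On each training split, thresholds are swept over
[min(S) − δ, max(S) + δ] in steps of δ = 0.25; accuracy(t) is the fraction
of samples with (S ≥ t) == (label == dMMR). Equally accurate thresholds
form a contiguous grid interval; the longest such run (rightmost on ties)
is kept and its midpoint evaluated on the held-out fold. The final cutoff
is the midpoint of the intersection of the fold-optimal intervals (union if
the intersection is empty), rounded to the nearest grid point with ties
upward — a deterministic formalisation of picking a round number from an
optimal band. Accuracy (not Youden's J or F1) is the objective throughout.

## Panel optimization

* **Per-locus AUC.** The diagnostic value of locus *i* is the Mann–Whitney
  AUC of *p<sub>i</sub>* for dMMR vs pMMR (ties counted ½), computed per
  cancer type and overall.
* **Greedy forward selection.** Loci are ordered by descending
  endometrial-cancer AUC (the hardest type; ties broken by locus id), then
  visited in order: a locus is kept iff adding its proportion to the
  running score sum raises the overall AUC by more than `tol` = 1e-6
  (strict improvement). The selection AUC is computed on the full labelled
  cohort — the same overfitting caveat that applies to any wrapper
  selection applies here, so the per-locus AUCs can also be computed on a
  held-out subset by filtering the cohort first.
* **Normal-tissue QC.** A locus is dropped when its mean depth across
  normal (e.g. leukocyte-DNA) samples is below 50 (failed amplification)
  or its mean background proportion exceeds τ = 0.30 (high variability).
  τ is this package's choice: the MSS baseline works out to ≈ 0.06–0.11
  per locus, so 0.30 flags loci whose stutter would drown somatic signal
  while not touching healthy markers.
* **Clustering.** Loci are clustered on the Euclidean distance between
  their per-type AUC vectors with average linkage. The linkage is computed
  by a direct O(n³) agglomeration with a documented tie rule (lowest
  cluster indices merge first), so dendrograms are reproducible
  independent of library version; heights agree with
  `scipy.cluster.hierarchy.linkage(method="average")`.
* **Differential variability.** Per locus, a two-sided rank-sum test of
  dMMR vs pMMR proportions within a cancer type, Benjamini–Hochberg
  adjusted across loci within the type. Adjustment is switchable off.

## Performance statistics

dMMR is the positive class and MSI-H the positive prediction everywhere.
Sensitivity, specificity and accuracy carry exact Clopper–Pearson binomial
intervals (inverted tail tests via beta quantiles; at x = n the lower bound
is (α/2)^(1/n)). ROC AUC is the Mann–Whitney statistic; its interval is a
stratified bootstrap percentile (2000 resamples, seeded) by default, with
DeLong's asymptotic interval as an alternative. Group comparisons of MSI
degree use one-way ANOVA computed from between/within sums of squares and
all-pairs Tukey HSD via the studentized-range distribution with the
Tukey–Kramer allowance for unequal group sizes; group means carry t-based
intervals from the pooled variance. The purity check is a Spearman rank
correlation of tumor purity against score among MSI-H samples.

## The simulator

The generator defines the package's study conditions; statistics modules
are exercised on its cohort path (proportions drawn directly) and the
caller on its read path (FASTQ written locus by locus). Both share one
model. Per sample and locus:

    p = stutter + f · effect(type) · severity · 1{locus affected}   (MSI-H)
    p = stutter                                                     (MSS)

* **Stutter**: Normal(0.08, 0.03) per locus, truncated to [0, 0.3], times
  a per-sample scale factor max(0.4, Normal(1, 0.15)). The scale factor
  models specimen-level background differences; without it MSS scores
  collapse to a point (sd ≈ 0.3), whereas the observed clinical MSS band
  spans roughly 5–10 score units.
* **Effects**: an MSI-H sample has each locus affected with probability
  0.5; the per-type effect is solved so that the expected score at the
  calibration purity f = 0.8 on 81 loci equals the observed group means —
  19.5 (colon), 16.2 (stomach), 13.3 (endometrium) — giving 0.402, 0.300
  and 0.210. The per-sample severity factor max(0, Normal(1, 0.2)) plus
  the binomial affected count give a score sd ≈ 3, matching the observed
  group spreads. Endometrial tumors thus carry genuinely weaker signal,
  which reproduces the clinically harder UCEC classification.
* **Purity**: scores dilute linearly, S(f) = f·S_T + (1−f)·S_N, by
  elementwise proportion mixing (equal amplification efficiency assumed).
  Default purity is fixed at the calibration value 0.8; an optional
  uniform per-sample purity range exists for dilution studies.
* **Depth**: gamma-Poisson (negative-binomial) with mean 827 and shape
  1.48, i.e. median ≈ 650 and quartiles ≈ (331, 1134). No negative
  binomial with median 650 can also reach the heavier observed upper
  quartile (~1659); matching the median and lower quartile was preferred
  since depth mainly matters through the low tail (QC dropout).
* **Reads**: variant tract lengths are deletion-biased (3:1) with
  geometric magnitude (mean 1.5). Scoring only consumes variant vs
  non-variant, so results are insensitive to this choice. Substitution
  errors (rate 0.002/base) are applied outside the anchor regions;
  anchor-error robustness is exercised separately by unit tests.
* The observed cohort entry is Binomial(depth, p)/depth; zero-depth loci
  are missing (NaN).

A separate planted-cohort generator supports selection benchmarks: 10
informative loci among 81, each carrying a large effect (0.7) in a block of
MSI-H samples exclusive to it plus a shared pool, over a bounded uniform
stutter background. The exclusive blocks make every informative locus
strictly necessary — the greedy trajectory must rise at each true locus —
and the bounded background makes the full planted set perfectly separating,
so no noise locus can improve on it.

**What the simulator does not emulate**: label noise (IHC
misinterpretation, subclonal MMR loss — the generator's labels always match
its ground truth), FFPE artifacts, locus-specific stutter spectra,
primer-dimer and off-target reads, base-quality variation, and
amplification-efficiency differences between alleles. Passing recovery
tests therefore demonstrates the pipeline's correctness under the stated
generative model, not clinical performance; the published clinical metrics
require the clinical cohort.

## Numerical conventions

* Proportions are fractions in [0, 1]; percentages appear only in reports
  (half-up integer rendering, with one-decimal precision additionally used
  for sensitivity in text).
* Coordinates are 0-based half-open everywhere; BED export matches.
* Scores at exactly the cutoff are MSI-H; grid rounding ties go upward.
* AUC ties count ½; undefined AUCs (single-class subsets) are reported
  missing and imputed at 0.5 only inside clustering, with a warning.
* Determinism: every stochastic routine takes a seed or Generator;
  identical seeds give byte-identical outputs, and results are invariant
  to read order and locus order.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the simulated reference
cohort at 294 samples (the published class mix), selection benchmarks at
600 samples × 81 loci over 20 seeds, and the read-level end-to-end check at
40 samples × 81 loci at full default depth (~2.7 M reads); these sizes give
stable statistics while keeping a full run in the low minutes on one core.

## Known limitations

* Anchors are matched by Hamming distance; an indel inside a flank shifts
  the anchor and fails the read rather than recovering it.
* Mate-pair double counting halves the nominal binomial standard error of
  p_i for overlapping pairs.
* The 27-locus reduced panel of the clinical study cannot be reproduced
  from synthetic data; the selection machinery is validated by
  parameter-recovery instead.
* No MSI-intermediate category is defined; the classifier is binary with a
  FAILED escape for QC dropouts.
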