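# msiscore

Microsatellite-instability (MSI) detection and quantification from targeted
amplicon NGS of mononucleotide repeats.

Tumors with deficient mismatch repair (dMMR) accumulate indels in
homopolymer tracts. This package implements the full assay workflow for a
small amplicon panel of such tracts, for people building or validating
MSI tests (molecular-diagnostics developers, cancer genomics researchers):

* **panel model** — mononucleotide-repeat panel definitions (TSV/BED,
  0-based half-open), with flank sequences stored so no reference genome is
  needed;
* **repeat caller** — alignment-free, flank-anchored measurement of
  homopolymer length per read from FASTQ;
* **MSI score** — per locus *i*, the fraction *p<sub>i</sub>* of reads
  whose tract length differs from the reference, summed into
  S = Σ<sub>i</sub> p<sub>i</sub>; samples with S ≥ c are MSI-H
  (c = 10 on the 81-locus panel, c = 4 on the reduced 27-locus panel);
* **cutoff cross-validation** — stratified k-fold threshold sweep against
  dMMR/pMMR reference labels;
* **panel optimization** — per-locus Mann–Whitney AUC by cancer type,
  normal-tissue baseline QC, average-linkage locus clustering, rank-sum
  differential tests, and greedy forward locus selection;
* **performance statistics** — sensitivity/specificity with exact
  Clopper–Pearson intervals, bootstrap/DeLong AUC intervals, ANOVA + Tukey
  HSD comparisons of MSI degree across cancer types;
* **simulator** — synthetic cohorts and FASTQ reads with known ground
  truth (PCR stutter, cancer-type effect sizes, depth variation, linear
  tumor-purity dilution), so every stage is testable without clinical data.

The scoring needs no patient-matched normal sample: the MSS stutter
baseline is handled by the cutoff, not by subtraction.

## Worked example

Score a simulated MSI-high colon-cancer sample straight from reads
(`examples/01_score_a_sample_from_reads.py`):

```text
reads seen      : 59191
reads assigned  : 59191
loci passing QC : 80/81
MSI score       : 27.71
status          : MSI-H
```

All 59 191 amplicon reads contained both flank anchors of exactly one
locus; one locus fell below the depth floor (50 reads) and the score was
rescaled by 81/80. The score 27.71 is the summed variant-read fraction
over the panel — far above the cutoff 10, so the sample is called MSI-H.
An MSS sample at the same settings scores ≈ 6.5 (pure PCR stutter).

Choosing the cutoff by fourfold cross-validation on a simulated
294-sample reference cohort (`examples/02_cutoff_cross_validation.py`):

```text
samples               : 294
optimal interval      : [8.99, 10.10]
chosen cutoff         : 9.5
cross-validated acc.  : 0.990
```

The accuracy-optimal threshold band straddles 9–10 with held-out accuracy
0.99, which is why 10 is the standard 81-locus cutoff.

The other examples cover greedy panel reduction (`03`), diagnostic
performance with exact confidence intervals (`04`), purity dilution and
the closed-form cutoff crossing (`05`), and MSI-degree comparison across
colon/stomach/endometrial cancers (`06`). Each prints what it computes and
what the numbers mean.

## Command line

A thin CLI wraps the same functions:

```bash
msiscore simulate cohort --seed 1 --out cohort.tsv
msiscore score --cohort cohort.tsv --out scores.tsv
msiscore evaluate --scores scores.tsv --cohort cohort.tsv --out metrics.tsv
msiscore call reads.fastq.gz --out calls.tsv        # FASTQ -> locus TSV
msiscore cv-threshold --cohort cohort.tsv --out cv.json
msiscore select-loci --cohort cohort.tsv --out selection.json
```

Subcommands: `panel validate|convert`, `call`, `score`, `cv-threshold`,
`select-loci`, `cluster-loci`, `evaluate`, `compare-degree`,
`simulate cohort|reads`. Outputs are plain TSV/JSON with provenance
sidecars; identical command + seed gives identical output.

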