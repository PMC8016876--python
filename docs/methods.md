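# Methods

`txaging` reimplements, as a tested library, an age-association analysis
of bulk skeletal-muscle RNA-seq: per-gene differential expression under
two model families with a consensus intersection, differential transcript
usage (DTU) on the isoform-percentage scale, group-wise differential exon
usage, and mRNA–protein coefficient correlation. Every stage can be
exercised on synthetic count data whose generating parameters are known,
so calibration and recovery are measurable.

## Count model and normalization

Counts are modelled as negative binomial (NB), parameterized by
(mean μ, size k) with variance μ + μ²/k; larger k means less
overdispersion. Two normalized scales are used:

- **log2(CPM)** — counts per million, log2-transformed, for the linear
  (Gaussian) models. The default pseudo-count is 0: a zero count maps to
  −∞, which fails every `≥` filter by construction. This preserves the
  exact equivalence of the printed filter threshold (log2CPM ≥ −3 is
  precisely 10 reads in an 80-million-read library); a configurable
  pseudo-count is available for plotting.
- **rounded CPB** — counts per billion, rounded half-up to integers, for
  the count-family models, which need integer responses. Rounding at the
  CPB rather than CPM scale keeps relative rounding error small. CPB ≥ 125
  is the same 10-reads/80M cut on this scale.

Library sizes default to column sums (the total aligned reads of the
original experiment are not recoverable from a filtered count table) and
can be supplied externally. No TMM/DESeq-style composition correction is
applied — the analysis this package reproduces used none. A consequence,
reproduced faithfully here and visible in the synthetic-data experiments:
when a large fraction of genes moves in one direction with age, CPM/CPB
normalization induces an opposite-signed trend in unaffected genes. At
the study-like prevalence of ~2% age-associated genes this bias is
negligible (|bias| ≪ 1 SE of a typical slope).

### Filtering cascade

1. Features with zero counts in every sample are removed.
2. Linear branch: keep features with ≥ 10 samples at log2CPM ≥ −3.
3. Count branch: keep features with ≥ 10 samples at CPB ≥ 125; then
   exclude features with zero CPB in > 50 samples ("excess zeros") or
   median CPB < 630 ("low median"). Every exclusion is recorded with its
   reason.

## Differential expression

Each retained gene is tested for a continuous age trend with age and sex
as the only covariates.

- **Linear family**: OLS of log2(CPM) on intercept + age + sex; Wald t
  test with n − p df. Samples at the zero-count sentinel are excluded
  from that gene's fit (the alternative — flooring — lets an arbitrary
  floor dominate the slope; both behaviours are available).
- **Count family**, routed purely by the presence of a zero CPB value:
  - no zeros → NB regression (log link), gene-wise dispersion by maximum
    likelihood with a method-of-moments start, Newton optimizer with BFGS
    fallback; Wald z test.
  - ≥ 1 zero → **hurdle** model: logistic regression of the zero/nonzero
    indicator plus a zero-truncated NB on the positive counts, both on
    intercept + age + sex. The zeros are treated as structural (true
    absence), which is why a hurdle rather than a zero-inflated mixture
    is used. The gene's headline coefficient and p-value come from the
    truncated-count component — it models expression level among
    expressing samples, the same target as the linear model — with the
    zero component's coefficients reported alongside. Perfect separation
    in the logistic part falls back to a penalized fit and is flagged;
    genes with < 5 positive samples are excluded with a reason.
- **Consensus**: genes with p < α (default 0.01, unadjusted — BH
  adjustment is available as an option) in *both* families and agreeing
  coefficient signs, labelled up/down. Ranked lists break ties by
  ascending p, then |β| descending, then feature id.

Because both families fit the same counts, their test statistics are
strongly dependent: the consensus is *not* close to an independent
product of error rates, and its false-positive set can coincide with the
smaller family's. Consequently, at realistic prevalence (~2%) and
unadjusted p < 0.01, a sizeable fraction of the consensus set consists of
false positives; the intersection buys robustness against
family-specific artifacts, not multiplicative error control. The test
suite therefore checks sign concordance with the generating truth among
consensus genes that carry true effects, and reports consensus precision
as its own quantity.

The 2-SE Wald interval of the NB age coefficient has measured coverage
≈ 94–95% at n = 300 (ML dispersion makes the Wald SE slightly
anticonservative); parameter-recovery checks sit at that boundary by
construction.

## Differential transcript usage

Each transcript's reads per sample are expressed as a percentage of the
sample's total over all transcripts of the same gene; the percentage is
undefined (flagged) when the gene total is zero. Per-transcript OLS of
usage on age (+ sex by default, switchable to age-only) with a Wald test;
default α = 0.05 for targeted scans, 0.01 for the genome-wide pass —
both are parameters, neither hard-coded, and p-values are unadjusted with
a BH option. A parallel regression on the absolute log2(TPM + 1) scale
supports the percentage-vs-absolute contrast: a transcript whose usage
share falls while its gene total rises can have a flat absolute trend.
Within a gene, usage percentages sum to 100 per sample, so fitted usage
slopes sum to 0 — both are tested invariants.

TPM computation from counts requires effective lengths; when lengths are
unavailable the TPM table must be supplied precomputed.

## Differential exon usage

For each exon, the per-sample response pair is (reads on this exon, reads
on the rest of the gene). The stacked pairs are fit by an NB GLM with
log link, terms `group + bin + group:bin` (bin = this-exon vs rest) and
offset log(per-sample gene total), so coefficients model the exon's
within-gene share; the interaction is tested by a 1-df likelihood-ratio
chi-square. This is the core exon-vs-rest contrast of the DEXSeq-style
design, simplified from the full per-sample fixed-effects model.

Dispersion is estimated **once** per exon, by method-of-moments against
the full model's Poisson fit, and held fixed in both the full and
reduced fits. This is essential: letting the reduced model refit its own
dispersion allows it to absorb the interaction signal into
overdispersion and deflates the LRT to zero even for dramatic effects.
Moment estimation (rather than ML) also behaves on degenerate and
underdispersed fixtures, where ML dispersion diverges. P-values are BH
adjusted across all exons tested in one run; default FDR threshold 0.1.
Single-exon genes and exons whose gene total is zero in nearly all of a
group are skipped with a reason. Exon coordinates, when provided, are
exported 0-based half-open (BED convention).

The intersection with the DTU scan takes both thresholds (exon FDR, DTU
raw p) as parameters, since the two analyses use different scales of
evidence.

## mRNA–protein correlation

Per-gene Pearson (or Spearman) correlation between log2CPM and relative
protein abundance across shared samples; pairs with < 3 shared samples or
a zero-variance vector are flagged, not silently dropped. Protein age
coefficients are estimated with exactly the same linear machinery as the
mRNA side (intercept + age + sex), and the two coefficient vectors are
compared by correlation for the full gene set and for an age-selected
subset. A random same-size gene subset, sampled without replacement with
a recorded seed, provides the control against which the selected subset's
coherence is judged.

## Reporting utilities

- Volcano tables classify fits into up/down/ns at a given α; p = 0 is
  capped on the −log10 scale.
- Heat-map input: row-wise z-scores with the sample (n − 1) SD convention
  (declared so the unit-SD invariant is testable); row order from
  complete-linkage hierarchical clustering on the distance 1 − Pearson r
  between rows. Constant rows cannot be standardized or correlated; they
  are flagged and placed last. Ties resolve by input row index; leaf
  order follows the standard recursive traversal (subtree orientation is
  a display convention, so the clustering test compares merge structure
  against a brute-force oracle, not leaf order).
- Kruskal–Wallis two-group comparison: rank-based H with ties correction,
  p from χ²(1). For 5 + 5 groups the χ² p is within 0.005 of the exact
  permutation p over all 252 splits (tested). Identical pooled values
  give H = 0, p = 1.
- Relative expression: elementwise target/reference ratio (e.g.
  normalization to a housekeeping gene); zero references yield flagged
  missing values.

## Synthetic-data generator

The generator emulates the cohort and the statistical structure the
pipeline assumes: 53 samples with ages uniform over 22–83 years (a fixed
age vector can be supplied for exact reproducibility), sex 0/1 assigned
near-equally and independent of age, and NB gene counts with
mean μ_g·exp(β_g·(age − midpoint) + γ_g·sex).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_samples, age_range | 53, (22, 83) | the cohort the analysis targets |
| frac_age_assoc | 0.02 | ~2% of annotated RNAs changed with age in the motivating study |
| beta_age_effect | 0.02 /yr | a 3.4-fold change across the 61-year span — the scale of the strongest reported trends |
| frac_positive | 0.9 | age-associated transcriptomes skew positive |
| dispersion_range | (2, 50) | from strongly overdispersed to near-Poisson |
| baseline_mean_range | (20, 500) | moderately to well-expressed genes (filters pass) |
| frac_structural_zero_genes | 0.05 | exercises the hurdle branch |
| usage_drift_magnitude | 0.3 pp/yr | an ~18-point usage shift over the age span |
| protein_corr_target | 0.6 | a clearly coupled mRNA–protein pair |

Structural zeros are implemented by masking a per-gene random sample
subset (zero fraction uniform 0.3–0.9) to zero, drawn once and recorded
in the truth table — zeros are independent of age by construction, which
is exactly the structural-zero assumption the hurdle model makes.
Isoform counts split each gene's count multinomially across 1–4
transcripts; drift genes move the first transcript's proportion linearly
with age, balanced by equal losses across the rest, clamped to the
simplex (clamping is warned about because it bends the nominal linear
trend). Transcript counts sum to gene counts exactly, per sample.
Protein abundances for the coupled subset are log2CPM plus Gaussian noise
with SD chosen analytically so the expected Pearson correlation equals
the target; other genes get independent noise.

What the generator does **not** emulate: GC/length bias, batch effects,
sampling (non-structural) dropout, correlated genes, non-uniform age
distributions, or read-level artifacts. Passing tests therefore
demonstrate statistical correctness of the pipeline under its own
assumptions, not robustness to those real-data complications.

For group-wise synthetic analyses the young/old labels are age ≤ 34 vs
age ≥ 65: with ages uniform over 22–83, an 80+ stratum would hold only
~3 samples, too few for a stable group contrast at desk scale.

## Problem sizes used in the checks

Null calibration runs 2,000 genes × 53 samples; parameter recovery uses
100 replicate genes at n = 300 for each of the NB and hurdle branches;
power/concordance uses 1,000 genes at n = 53; the DTU/exon
cross-consistency check pools 10 seeded runs of 40 genes; the
filter-arithmetic check builds the full 57,773-feature annotation-scale
matrix. These sizes keep each run deterministic and fast while leaving
the Monte-Carlo error of the reported fractions well below the margins
being tested.

## Known limitations

- The exon test approximates the reference per-sample fixed-effects GLM
  with a group-level design; its dispersions are moment-based, not
  shrunken across exons.
- Zero-inflated NB (mixture) models are deliberately not implemented;
  only the hurdle form is, matching the structural-zero assumption.
- The hurdle's zero-component inference under perfect separation is
  penalized and flagged rather than exact.
- No gene-level multiple-testing correction by default (faithful to the
  unadjusted thresholds it reproduces); BH is available everywhere as an
  option.
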