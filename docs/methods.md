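# Methods

This note documents the models and procedures implemented in `mtqq`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions.

## Heteroplasmy and homoplasmy calling

Input is an `AlleleCountTable`: per position (1-based, 16,569 bp
mitochondrial genome), per base (A<C<G<T order), per strand, the read
counts that survived base-quality filtering (phred ≥ 20 applied at
ingestion). The caller assumes upstream read processing has already
enforced unique mapping to the mitochondrial genome, proper pair
orientation and < 5 mismatches — the standard defence against NUMT
(nuclear-embedded mtDNA) artefacts — and deduplication; these are
documented ingestion preconditions, not re-checked.

A heteroplasmy call requires all of:

| criterion | default | convention |
|---|---|---|
| depth | 200 reads | strict `>` |
| minor-allele fraction | 0.02 | inclusive `≥`, MAF ≤ 0.5 by definition |
| minor reads per strand | 2 | inclusive `≥` on *each* strand |

MAF uses the post-quality-filter depth as its denominator (the same counts
the thresholds are applied to). At multi-allelic sites the minor allele is
the second-most-frequent base; ties break by the fixed base order A<C<G<T;
additional alleles are ignored. Indels are out of scope. Homoplasmies are
consensus substitutions: consensus ≠ reference with consensus fraction
≥ 1 − min_maf (0.98) and the same depth rule — a frequency rule chosen so
that downstream consumers (haplogrouping, the common-variant scan) need
only substitution genotypes. Down-sampling thins every count binomially
with p = target/current base total, so 60,000 reads of 100 bp give an
expected ~362× over 16,569 bp.

## Contamination screen

Two criteria must *both* hold: (1) the sample's heteroplasmy count strictly
exceeds Q3 + 1.5·IQR of the cohort counts (quartiles by linear
interpolation, the common numpy default; the multiplier is configurable),
and (2) the haplogroup assigned to the sample's major-allele consensus
differs from the haplogroup of its minor-allele consensus (minor alleles
substituted at heteroplasmic sites). Quartiles are computed in a single
pass over all samples, before any exclusion. The cohort-derived threshold
is never hard-coded; a cohort whose quartiles imply 8 will suspect samples
with more than 8 heteroplasmies.

Haplogroup assignment is a flat defining-variant matcher: the haplogroup
maximising matched/total defining variants, ties broken by more absolute
matches then lexicographically. No phylogenetic traversal is attempted —
the screen only needs a same-vs-different decision, for which the flat
matcher is sufficient when haplogroups differ at ≥ 10 defining sites.

## Copy number

With two copies of each autosome per cell, coverage is proportional to
copy number, so

    copy_number = 2 · mean(MT) / [ (1/22) Σᵢ mean(autosomeᵢ) ]

The autosomal aggregate is deliberately the unweighted mean of the 22
per-contig mean depths (not a length-weighted genome-wide mean); the
estimate is scale-invariant, and undefined (an error) at zero nuclear
coverage. Cohort descriptives report the adjusted Fisher–Pearson skewness
and the D'Agostino skewness test (≥ 8 samples; constant data reports
skewness as undefined).

## Annotation and pathogenicity

Each call gets a single-label region via the priority protein_coding >
tRNA > rRNA > control_region (the control region is one locus with the
origin-spanning intervals 16024–16569 and 1–576), a coding effect under
the vertebrate mitochondrial code (minus-strand genes reverse-complemented
before codon extraction; substitutions in a partial terminal codon are
classified noncoding with a warning), a scaled pathogenicity score from a
CADD-like lookup table, and a disease-catalog flag. A variant is
*pathogenic* when score ≥ cutoff; the boundary is inclusive and the cutoff
(default 15) is swept over 12–22 to guard against the arbitrary choice.
Missing scores leave the flag absent and are counted in a warning; score
comparisons exclude them. Unique-variant views deduplicate by (position,
alt) so recurrent variants count once.

The per-locus enrichment test is a one-vs-rest 1-df chi-square goodness of
fit: observed (count in locus, count in rest of category) against the
length-proportional expectation, with an exact binomial fallback (flagged)
when an expected count falls below 1. This concrete definition is isolated
behind `locus_outlier_test` so it can be swapped.

## Association battery

All fits are OLS with intercept and listwise deletion, reported as
`RegressionResult` objects (estimates, SEs, two-sided t-based p-values,
`summary()`). The joint models use **age as the response** with burden and
copy number as predictors; this is a convenience regression testing
whether each mtDNA property carries age information not explained by the
other, not a causal model, and is reproduced verbatim because that is the
form its results tables are stated in. The copy-number-vs-age simple
regression includes no further covariates. The phenotype scan fits
trait ~ feature + age per trait on untransformed traits (a log flag is
available), flags at Bonferroni fwer/m over the traits actually scanned,
and standardises effects as β·SD(feature)/SD(trait). The common-variant
scan tests only variants carried by strictly more than 1 % of samples,
adjusting for age and mean nuclear coverage. Haplogroup scans are
carrier-vs-rest terms with covariates; singleton haplogroups pool into
"other". Age-group tables use left-closed bins (<40, 40–50, 50–60, 60–70,
>70) and MAF strata [0.02, 0.05] and (0.05, 0.5] — the 0.05 boundary
belongs to the low stratum, so stratum means sum exactly to the total.
The two-proportion chi-square uses no continuity correction.

## Weighted kernel association test

Let X be the n×m genotype matrix over the cohort's union heteroplasmic
sites. Cell (i, j) re-counts individual i's quality-filtered bases at site
j and records i's own minor-allele (second-most-frequent base) fraction —
only when that minor count strictly exceeds 5, else 0; binary mode records
the indicator instead. Counting the *sample's own* minor allele matters: at
population-polymorphic sites the union site's named allele is the major
allele of every non-carrier, and counting it would fill the column with
~0.5s. Sites whose position is homoplasmic in more than 1 % of samples
("polymorphic") are excluded; this concrete definition sits behind the
`exclude_polymorphic` argument so callers can redefine it.

The null model is OLS of the (optionally log-transformed) phenotype on
[1, C]; C defaults to age, copy number, and the top two principal
components of the centered homoplasmy 0/1 matrix as a population-structure
proxy (nuclear genotypes being outside this package's inputs — a
documented substitution). With residuals r and W = diag(w),

    Q = r' X W² X' r

and under the null Q ~ Σ λₖ χ²₁ with λ the eigenvalues of
σ̂²·(P₀XW)'(P₀XW), P₀ the projection off the covariate space. The analytic
p-value matches the first three cumulants (and kurtosis) of the mixture to
a scaled non-central chi-square; with a single eigenvalue this is exact and
the test reduces to the squared score test of one covariate-adjusted
regressor. The moment-matching tail is validated two ways: a residual
permutation oracle (p = (1 + #{Q* ≥ Q})/(1 + B), deterministic given a
seed) agreeing rank-wise (Spearman ρ > 0.9), and an empirical null
type-I error at α = 0.05 inside [0.035, 0.065] over 2000 replicates.
Weights are the raw scaled pathogenicity scores (no beta-density
transform — the weighting intent is simply to upweight predicted-
deleterious variants); missing weights become the median observed weight,
with a warning. Only the continuous-trait (linear) test is implemented;
SKAT-O, burden tests and small-sample kurtosis corrections are out of
scope. `Q` is invariant under invertible affine reparameterisations of C,
and doubling all weights quadruples Q while leaving p unchanged.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline is meant to
operate under; they are fixed, not tuning knobs.

* **Ages**: truncated normal, mean 55.5 y, SD 12.8 y, support 17.3–84.5 y.
* **Burden**: per-individual heteroplasmy count ~ Poisson(0.30 +
  0.011·age). The intercept 0.30 makes the cohort mean burden ≈ 0.9 and
  the total ≈ 1350 calls at n = 1511. A strictly linear intensity slightly
  overstates the young-vs-old contrast relative to a table of observed
  group means (the >70 vs <40 ratio comes out ≈ 1.7 rather than ≈ 1.6);
  the linear law is kept because the slope, the mean burden and the total
  count are the primary recovery targets.
* **MAF law**: mixture 0.77·TruncBeta(1.2, 55) + 0.23·Uniform on
  (0.02, 0.5]. A single truncated beta cannot put ~63 % of mass below 0.05
  *and* ~20 % above 0.10; the two-component law reproduces both. Observed
  (called) spectra sit ~3–6 points lower in the <5 % bin because calls near
  the 2 % threshold fall below it by binomial sampling.
* **Positions**: drawn genome-wide with 6× per-bp enrichment in the
  control region (its hypervariability), alternate alleles uniform over
  the three non-consensus bases; 14 % of variants are drawn from the
  disease catalog.
* **Copy number**: 130 − 0.395·age + Gamma(shape 1.664, scale 58.8),
  floored at 10. The gamma residual gives skewness 2/√1.664 ≈ 1.55 and a
  cohort median ≈ 188. The implied mean (~205) exceeds the median, as any
  positively skewed law requires; a stated mean *below* the median is not
  simultaneously satisfiable and the generator targets skew and median.
* **Sequencing**: per-sample MT mean depth = copy_number ×
  nuclear_depth/2 (the coverage-ratio identity holds by construction);
  nuclear depth ~ N(5.5, 0.4) so mean MT coverage ≈ 568×. Count tables are
  drawn as independent Poisson cells (equivalent to Poisson total depth
  multinomially split over base × strand), strands split 1:1 (no
  strand-bias model), substitution errors uniform at 2×10⁻³ per read base —
  low enough that error alleles essentially never pass the 2 %/strand
  filters at these depths. Heteroplasmic sites are drawn binomially at
  their true MAF.
* **Homoplasmies**: each sample carries its haplogroup's defining variants
  plus ~Poisson(2) private substitutions. The built-in haplogroup table is
  synthetic: ten lineages named after common European haplogroups
  (frequencies H 48.5 %, U 14.6 %, K 9.5 %, J 8.9 %, T 8.3 %, …), each
  defined by 12–18 variants at disjoint positions.
* **Pathogenicity scores**: bimodal normal mixtures per coding-effect
  class (a benign and a deleterious mode), with nonsynonymous
  heteroplasmies carrying more deleterious-mode mass (weight 0.66 at
  MAF ≤ 10 %, 0.45 above) than homoplasmies (0.38). This yields
  nonsynonymous score means ≈ 14.5 (het) vs ≈ 10.9 (hom), above-15
  fractions ≈ 0.52 vs ≈ 0.34 (ratio ≈ 1.5 at the default cutoff), and a
  significant low-vs-high-MAF contrast at the 10 % boundary that fades as
  the boundary drops toward 6 %. A single normal per class cannot produce
  a mean near 14.3 with more than half the mass above 15. Disease-catalog
  variants score N(17.4, 4).
* **Phenotypes** (32 traits): bicarbonate (mean 26, SD 2.65 mmol/L) at
  +0.102 SD and WBC (mean 7, SD 2 ×10⁹/L) at −0.116 SD per SD of *true*
  copy number; platelets null; ApoB log-normal with log-scale coupling
  0.40 SD per SD of the standardized sum of the score×MAF load and the
  score-weighted occupancy load (so both genotype-matrix modes carry
  signal); 28 null log-normal traits. Measured power of the kernel test
  against this ApoB coupling at n = 1511 (rejection at the 32-trait
  Bonferroni level): effect 0.1 → ~5 %, 0.15 → ~15 %, 0.2 → ~50 %,
  0.3 → ~85 %, 0.4 → ~100 %; 0.40 is the default because it reproduces
  p-values of the order observed in cohorts of this size.
* **Contamination**: chosen pairs from different haplogroups are mixed by
  binomial thinning, thin(a, 1−f) + thin(b, f), default f = 0.10.

Everything is reproducible bit-for-bit from the config seed.

**What passing tests on these cohorts does and does not show.** The
generator emulates count-level statistics, not reads: there is no
alignment, no NUMT leakage, no PCR-duplicate structure, no strand bias, no
per-position error spectrum, no twin/kinship structure, and variants are
independent across individuals (no shared clonal lineages beyond
haplogroups). Pipeline correctness (thresholds, formulas, calibration,
operating characteristics) transfers to real data; empirical effect sizes
do not.

## Problem sizes

The test suite exercises full-size cohorts (n = 1511) for slope recovery
across 20 seeds, 600–2000-sample cohorts for distributional checks, 50
replicated 36-sample cohorts for the contamination screen, and 2000 null
replicates for kernel-test calibration. The acceptance script uses one
1511-sample pipeline run, 20 further full-size cohorts for slope
averaging, 150 samples for caller exactness, and the same screen and
calibration replicate counts; it completes in under ten minutes on one
CPU.

## Numerical conventions and degenerate inputs

1-based inclusive coordinates everywhere (BED converted on read); base
order A<C<G<T for all tie-breaks; linear-interpolation quantiles; OLS via
QR/least-squares with rank checks that name collinear terms; kernel-test
eigenvalues below max(λ)·1e-12 discarded; an all-zero genotype matrix
yields Q = 0, p = 1, flagged degenerate; empty call sets give empty
outputs (with warnings where a proportion would be undefined); PCA signs
fixed by making each component's largest-magnitude loading positive.

## Known limitations

Substitutions only (no indels, no length heteroplasmy in homopolymer
runs); no GC or mappability normalisation of coverage (deliberate — the
estimator mirrors the plain coverage-ratio definition); the flat
haplogroup matcher is not a phylogenetic placement and should not be used
for lineage reporting; the moment-matching tail is approximate in the
extreme tail (the permutation oracle is the fallback); population-structure
PCs from mitochondrial homoplasmies are a proxy for nuclear ancestry PCs.
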