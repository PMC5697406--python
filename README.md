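# mtqq — blood mtDNA quality and quantity from WGS allele counts

`mtqq` analyses the two properties of blood mitochondrial DNA that change
with age — its *quality* (the burden of heteroplasmic point mutations) and
its *quantity* (genomes per cell) — from whole-genome-sequencing summaries,
and tests how both relate to age and blood phenotypes in a population
cohort. It is written for statistical geneticists and mitochondrial
biologists who have per-site allele counts over the 16,569 bp mitochondrial
genome plus per-contig mean coverages, and want a tested, reproducible
version of the standard analysis battery rather than a pile of one-off
scripts.

## What it computes

**Heteroplasmy calling.** A site is heteroplasmic in an individual when,
after base-quality filtering (phred ≥ 20), sequencing depth is > 200, the
minor (second-most-frequent) allele reaches MAF ≥ 2 %, and the minor allele
is seen ≥ 2 times on each strand. Homoplasmies are consensus substitutions
(consensus ≠ reference at ≥ 98 %). Binomial down-sampling (e.g. to 60,000
reads ≈ 360×) supports coverage-robustness checks.

**Contamination screen.** A sample is excluded only when two signals agree:
its heteroplasmy count exceeds Q3 + 1.5·IQR for the cohort *and* the
consensus sequences built from its major and its minor alleles assign to
different mtDNA haplogroups.

**Copy number.** With two nuclear copies per cell, mtDNA copy number is

```
copy_number = 2 · mean(MT coverage) / (1/22) Σᵢ mean(autosomeᵢ coverage)
```

with the autosomal aggregate the unweighted mean of the 22 per-contig means.

**Annotation.** Region (control region / rRNA / tRNA / protein-coding with
synonymous vs nonsynonymous under the vertebrate mitochondrial code),
scaled pathogenicity score (CADD-like table; pathogenic at score ≥ 15, with
a 12–22 cutoff sweep), and disease-catalog membership.

**Association battery.** OLS regressions of burden and copy number on age;
the joint model `age ~ het_count + copy_number` (with and without WBC and
platelet counts); a 32-trait phenotype scan with Bonferroni control;
per-variant homoplasmy and haplogroup scans; age-group summary tables.

**Kernel association test.** A from-scratch weighted variance-component
score test of heteroplasmy load: with genotype matrix X (minor-allele
fractions, or 0/1 occupancy), per-site weights w (pathogenicity scores) and
covariates C (age, copy number, two population-structure PCs),

```
Q = r' X W² X' r,   r = residuals of log-phenotype on [1, C],  W = diag(w)
```

with the null distribution a weighted mixture of 1-df chi-squares handled
by moment matching, and a residual-permutation test as the independent
oracle. `KernelAssociationModel(y, X, C, w).fit()` returns a
`KernelTestResult` with `summary()`.

**Synthetic cohorts.** Because the motivating cohort data are controlled
access, `mtqq.simulate` generates cohorts with the same statistical
structure — ages ~ N(55.5, 12.8²) truncated to 17.3–84.5 y, burden
intensity 0.30 + 0.011·age, copy number 130 − 0.395·age + positively skewed
noise (median ≈ 188, skewness ≈ 1.55), MT coverage ≈ 568× tied to copy
number through the coverage-ratio identity, a low-MAF-skewed spectrum,
cross-sample contamination mixtures, and phenotype couplings (+0.102 SD
bicarbonate and −0.116 SD WBC per SD copy number; ApoB log-linear in the
weighted heteroplasmy load) — together with full ground truth.

## Worked example

```python
import numpy as np
from mtqq import CohortConfig, simulate_cohort, analyze_cohort

cohort = simulate_cohort(CohortConfig(n_individuals=600, seed=11,
                                      contamination_pairs=3))
results = analyze_cohort(cohort, seed=11)

print(f"samples analysed: {len(results.samples)} "
      f"({len(results.dropped)} dropped as contaminated)")
print(f"heteroplasmies: {results.total_heteroplasmies} "
      f"({100*results.carrier_fraction():.1f}% of individuals carry >=1)")
print(f"MAF spectrum (<5%, 5-10%, >10%): {np.round(100*results.maf_spectrum, 1)}")
print(results.age_models["het_vs_age"])
print(results.age_models["cn_vs_age"])
print(results.skat_results.query("trait == 'apob'")[["trait", "mode", "Q", "p"]]
      .to_string(index=False))
```

prints

```
samples analysed: 597 (3 dropped as contaminated)
heteroplasmies: 494 (58.0% of individuals carry >=1)
MAF spectrum (<5%, 5-10%, >10%): [58.5 20.6 20.9]
OLS: het_count ~ age  (n=597, R2=0.0134)
 term  estimate       se        p
const  0.377947 0.161939 0.019934
  age  0.008220 0.002889 0.004585
OLS: copy_number ~ age  (n=597, R2=0.0039)
 term   estimate        se            p
const 230.774023 14.711980 1.156771e-46
  age  -0.400983  0.262441 1.270695e-01
trait   mode           Q        p
 apob    maf  211.386451 0.000120
 apob binary 6840.411766 0.008819
```

The contamination screen removed exactly the three planted mixtures. The
fitted burden slope (0.0082 ± 0.0029 per year) and copy-number slope
(−0.40 ± 0.26 per year) recover the planted 0.011 and −0.395 within
sampling error at this cohort size, and the weighted kernel test links
ApoB to heteroplasmy load (p ≈ 1.2e-4 with the MAF-valued matrix) while
the other 31 traits stay null.

The same pipeline runs from the shell:

```
mtqq all --n 600 --seed 11 --contamination-pairs 3 --outdir reports/
```

writing per-stage reports (`heteroplasmies.csv`, `contamination.tsv`,
`copy_number.tsv`, `age_models.txt`, `phenotype_scan_cn.tsv`, `skat.tsv`,
…). Individual stages are exposed as `mtqq simulate | call | screen |
copynum | annotate | associate | skat`; real pileup input is read with the
six-column `samtools mpileup` dialect.

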