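"""The regression battery: age models, phenotype scan, homoplasmy and
haplogroup scans, age-group summary tables, and shared test utilities.

Every fit is ordinary least squares with an intercept, reported statsmodels
style: a :class:`RegressionResult` carries coefficient estimates, standard
errors, two-sided t-based p-values and a ``summary()`` table.

The convenience regressions use age as the response with heteroplasmy count
and copy number as predictors — a joint-independence test, not a causal
model: significance of both terms says each mtDNA property carries age
information not explained by the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "fit_linear",
    "age_models",
    "group_summary",
    "welch_t",
    "chi_square_prop",
    "bonferroni_alpha",
    "phenotype_scan",
    "homoplasmy_scan",
    "haplogroup_scan",
]

AGE_BIN_EDGES = (0.0, 40.0, 50.0, 60.0, 70.0, np.inf)
AGE_BIN_LABELS = ("<40", "40-50", "50-60", "60-70", ">70")
#: MAF stratum boundary: 0.05 belongs to the low stratum
MAF_STRATA = (("2-5%", 0.02, 0.05), (">5%", 0.05, 0.5))


@dataclass
class RegressionResult:
    """OLS estimates for one model; terms exclude nothing (intercept first)."""

    response: str
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    n: int
    rsquared: float

    def __post_init__(self) -> None:
        k = len(self.terms)
        if not (len(self.params) == len(self.bse) == len(self.pvalues) == k):
            raise ValueError("term/estimate vectors have unequal lengths")
        if self.n <= k:
            raise ValueError("more terms than observations")

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "estimate": float(self.params[i]),
            "se": float(self.bse[i]),
            "p": float(self.pvalues[i]),
        }

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.bse,
                "p": self.pvalues,
            }
        )

    def __str__(self) -> str:
        head = f"OLS: {self.response} ~ {' + '.join(self.terms[1:]) or '1'}  (n={self.n}, R2={self.rsquared:.4f})"
        return head + "\n" + self.summary().to_string(index=False)


def fit_linear(
    y, design: pd.DataFrame | dict, response: str = "y"
) -> RegressionResult:
    """OLS with intercept; listwise deletion of missing values; errors on a
    rank-deficient design naming the collinear terms."""
    X = pd.DataFrame(design).copy()
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name=response)
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    Xmat = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xmat.to_numpy())
    if rank < Xmat.shape[1]:
        # identify offending columns by greedy inspection
        bad = []
        cols: list[str] = []
        for c in Xmat.columns:
            trial = Xmat[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(str(c))
            else:
                cols.append(c)
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    fit = sm.OLS(y, Xmat).fit()
    return RegressionResult(
        response=response,
        terms=[str(c) for c in Xmat.columns],
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        pvalues=np.asarray(fit.pvalues),
        n=int(fit.nobs),
        rsquared=float(fit.rsquared),
    )


def age_models(
    het_counts,
    copy_numbers,
    phenotypes: pd.DataFrame,
    nuclear_coverages=None,
) -> dict[str, RegressionResult]:
    """The five cohort regressions.

    (i)   het_count ~ age                       (burden accumulation)
    (ii)  copy_number ~ age                     (copy-number decline)
    (iii) age ~ het_count + copy_number         (joint independence)
    (iv)  age ~ het_count + copy_number + wbc + platelets
    (v)   copy_number ~ het_count + age + nuclear_coverage

    ``phenotypes`` must carry 'age' and, for (iv), 'wbc' and 'platelets';
    samples are aligned positionally.
    """
    df = phenotypes.reset_index(drop=True).copy()
    df["het_count"] = np.asarray(het_counts, dtype=float)
    df["copy_number"] = np.asarray(copy_numbers, dtype=float)
    out = {
        "het_vs_age": fit_linear(df["het_count"], df[["age"]], "het_count"),
        "cn_vs_age": fit_linear(df["copy_number"], df[["age"]], "copy_number"),
        "age_joint": fit_linear(
            df["age"], df[["het_count", "copy_number"]], "age"
        ),
    }
    if {"wbc", "platelets"} <= set(df.columns):
        out["age_joint_blood"] = fit_linear(
            df["age"], df[["het_count", "copy_number", "wbc", "platelets"]], "age"
        )
    if nuclear_coverages is not None:
        df["nuclear_coverage"] = np.asarray(nuclear_coverages, dtype=float)
        out["cn_vs_het"] = fit_linear(
            df["copy_number"], df[["het_count", "age", "nuclear_coverage"]], "copy_number"
        )
    return out


def group_summary(calls_per_sample: dict[str, list], ages: pd.Series) -> pd.DataFrame:
    """Age-group table: per bin the mean age, its SD, n, and for each MAF
    stratum the mean heteroplasmy count and the carrier proportion.

    Bins are left-closed ([40, 50) is "40-50"); the 0.05 MAF boundary belongs
    to the low stratum, so stratum means sum to the total mean exactly.
    """
    rows = []
    ages = pd.Series(ages)
    bins = pd.cut(
        ages, bins=AGE_BIN_EDGES, labels=AGE_BIN_LABELS, right=False, include_lowest=True
    )
    for label in AGE_BIN_LABELS:
        members = ages.index[bins == label]
        row = {"age_group": label, "n": len(members)}
        if len(members) == 0:
            rows.append(row)
            continue
        row["age_mean"] = float(ages[members].mean())
        row["age_sd"] = float(ages[members].std(ddof=1)) if len(members) > 1 else np.nan
        counts_total, counts_lo, counts_hi = [], [], []
        for s in members:
            calls = calls_per_sample.get(s, [])
            counts_total.append(len(calls))
            counts_lo.append(sum(1 for c in calls if c.maf <= MAF_STRATA[0][2]))
            counts_hi.append(sum(1 for c in calls if c.maf > MAF_STRATA[1][1]))
        for name, vec in (
            ("total", counts_total),
            ("maf_2_5", counts_lo),
            ("maf_gt5", counts_hi),
        ):
            vec = np.array(vec)
            row[f"het_mean_{name}"] = float(vec.mean())
            row[f"carrier_prop_{name}"] = float((vec > 0).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def category_summary_by_age(
    annotated, ages: pd.Series, sample_of=lambda v: v.sample
) -> pd.DataFrame:
    """Per age bin, the proportion of heteroplasmies in each single-label
    class (control region, intergenic, rRNA, tRNA, nonsynonymous,
    synonymous); rows sum to 1."""
    ages = pd.Series(ages)
    bins = pd.cut(
        ages, bins=AGE_BIN_EDGES, labels=AGE_BIN_LABELS, right=False, include_lowest=True
    )
    classes = ("control_region", "intergenic", "rRNA", "tRNA", "nonsynonymous", "synonymous")

    def klass(v):
        if v.category == "protein_coding":
            return v.effect if v.effect in ("nonsynonymous", "synonymous") else "nonsynonymous"
        return v.category

    rows = []
    for label in AGE_BIN_LABELS:
        members = set(ages.index[bins == label])
        sub = [v for v in annotated if sample_of(v) in members]
        row = {"age_group": label, "n_variants": len(sub)}
        for c in classes:
            row[c] = (
                sum(1 for v in sub if klass(v) == c) / len(sub) if sub else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_prop(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Chi-square test of two proportions (2x2, no continuity correction)."""
    if min(n1, n2) <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def bonferroni_alpha(m: int, fwer: float = 0.05) -> float:
    """Per-test significance threshold controlling the family-wise error rate."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return fwer / m


def phenotype_scan(
    feature,
    phenotypes: pd.DataFrame,
    age,
    traits: list[str] | None = None,
    fwer: float = 0.05,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per trait: OLS trait ~ feature + age; Bonferroni flag at fwer/m; the
    standardized effect is beta * SD(feature) / SD(trait)."""
    feature = np.asarray(feature, dtype=float)
    age = np.asarray(age, dtype=float)
    if traits is None:
        traits = [c for c in phenotypes.columns if c not in ("sample", "age", "haplogroup")]
    usable = []
    for t in traits:
        vals = np.asarray(phenotypes[t], dtype=float)
        if np.nanstd(vals) == 0:
            warnings.warn(f"trait {t!r} is constant; skipped", stacklevel=2)
            continue
        usable.append(t)
    alpha = bonferroni_alpha(len(usable), fwer)
    rows = []
    for t in usable:
        y = np.asarray(phenotypes[t], dtype=float)
        if log_transform:
            if np.nanmin(y) <= 0:
                warnings.warn(f"trait {t!r} non-positive; log skipped", stacklevel=2)
            else:
                y = np.log(y)
        res = fit_linear(y, {"feature": feature, "age": age}, response=t)
        beta = res["feature"]
        rows.append(
            {
                "trait": t,
                "beta": beta["estimate"],
                "se": beta["se"],
                "p": beta["p"],
                "effect_per_sd": beta["estimate"] * np.nanstd(feature, ddof=1) / np.nanstd(y, ddof=1),
                "significant": beta["p"] < alpha,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)


def homoplasmy_scan(
    copy_numbers,
    genotypes: pd.DataFrame,
    ages,
    nuclear_coverages,
    min_carrier_frac: float = 0.01,
    fwer: float = 0.05,
) -> pd.DataFrame:
    """Per-variant carrier (0/1) association with copy number, adjusted for
    age and mean nuclear coverage; only variants carried by strictly more
    than ``min_carrier_frac`` of samples are tested; Bonferroni over the
    number tested."""
    cn = np.asarray(copy_numbers, dtype=float)
    ages = np.asarray(ages, dtype=float)
    nuc = np.asarray(nuclear_coverages, dtype=float)
    carrier_frac = genotypes.mean(axis=0)
    tested = [v for v in genotypes.columns if carrier_frac[v] > min_carrier_frac]
    if not tested:
        return pd.DataFrame(
            columns=["variant", "carrier_frac", "beta", "se", "p", "significant", "alpha"]
        )
    alpha = bonferroni_alpha(len(tested), fwer)
    rows = []
    for v in tested:
        g = np.asarray(genotypes[v], dtype=float)
        if g.std() == 0:
            continue
        res = fit_linear(
            cn, {"carrier": g, "age": ages, "nuclear_coverage": nuc}, "copy_number"
        )
        term = res["carrier"]
        rows.append(
            {
                "variant": v,
                "carrier_frac": float(carrier_frac[v]),
                "beta": term["estimate"],
                "se": term["se"],
                "p": term["p"],
                "significant": term["p"] < alpha,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)


def haplogroup_scan(
    feature,
    haplogroups,
    covariates: pd.DataFrame | None = None,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Per haplogroup, a carrier-vs-rest linear model of ``feature`` with
    optional covariates; singleton haplogroups pool into 'other'."""
    feature = np.asarray(feature, dtype=float)
    labels = pd.Series(haplogroups).astype(str).reset_index(drop=True)
    sizes = labels.value_counts()
    labels = labels.where(labels.map(sizes) >= min_group_size, "other")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 haplogroups with sufficient members")
    rows = []
    for g in groups:
        design = {"carrier": (labels == g).astype(float)}
        if covariates is not None:
            for c in covariates.columns:
                design[c] = np.asarray(covariates[c], dtype=float)
        res = fit_linear(feature, design, "feature")
        term = res["carrier"]
        rows.append(
            {
                "haplogroup": g,
                "n": int((labels == g).sum()),
                "beta": term["estimate"],
                "se": term["se"],
                "p": term["p"],
            }
        )
    return pd.DataFrame(rows)
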