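"""End-to-end cohort analysis in the pipeline order:

call -> contamination screen (flagged samples dropped) -> copy number ->
annotate -> association battery -> kernel association test.

`analyze_cohort` is the library entry point (a SyntheticCohort or equivalent
ingested data in, a CohortResults out); the CLI is a thin wrapper that also
writes every stage's report to a directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import association as assoc
from . import contamination as contam
from . import copynumber as cn_mod
from . import io as io_mod
from . import kernel as skat_mod
from .calling import CallCriteria, call_heteroplasmies, call_homoplasmies, maf_spectrum
from .reference import vertebrate_mito_code
from .simulate import SyntheticCohort

log = logging.getLogger("mtqq")

__all__ = ["CohortResults", "analyze_cohort"]


@dataclass
class CohortResults:
    """Everything the pipeline computed, stage by stage."""

    samples: list[str]
    het_calls: dict[str, list]
    hom_calls: dict[str, list]
    contamination: pd.DataFrame
    dropped: list[str]
    copy_numbers: pd.Series
    annotated_het: list
    annotated_hom: list
    maf_spectrum: np.ndarray
    age_models: dict[str, assoc.RegressionResult]
    group_table: pd.DataFrame
    category_table: pd.DataFrame
    phenotype_scan_cn: pd.DataFrame
    homoplasmy_scan: pd.DataFrame
    haplogroup_scan_het: pd.DataFrame | None
    pathogenic_sweep: pd.DataFrame
    skat_results: pd.DataFrame
    extras: dict = field(default_factory=dict)

    @property
    def total_heteroplasmies(self) -> int:
        return sum(len(v) for v in self.het_calls.values())

    def carrier_fraction(self) -> float:
        return float(np.mean([len(v) > 0 for v in self.het_calls.values()]))


def analyze_cohort(
    cohort: SyntheticCohort,
    crit: CallCriteria = CallCriteria(),
    cadd_cutoff: float = 15.0,
    fwer: float = 0.05,
    contamination_multiplier: float = 1.5,
    skat_traits: tuple[str, ...] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> CohortResults:
    ref_seq = cohort.ref_seq
    code = vertebrate_mito_code()

    # stage 1: calling
    het_calls = {t.sample: call_heteroplasmies(t, crit) for t in cohort.tables}
    hom_calls = {t.sample: call_homoplasmies(t, crit, ref_seq) for t in cohort.tables}
    log.info("called %d heteroplasmies in %d samples",
             sum(map(len, het_calls.values())), len(cohort.tables))

    # stage 2: contamination screen; flagged samples leave the analysis
    reports = contam.screen_cohort(
        cohort.tables, het_calls, cohort.haplogroups, ref_seq,
        crit=crit, multiplier=contamination_multiplier,
    )
    report_df = contam.reports_to_frame(reports)
    dropped = sorted(report_df.loc[report_df.contaminated, "sample"])
    keep_mask = ~cohort.truth_samples["sample"].isin(dropped).to_numpy()
    samples = [s for s in cohort.samples if s not in set(dropped)]
    tables = [t for t in cohort.tables if t.sample not in set(dropped)]
    log.info("contamination screen dropped %d samples", len(dropped))

    het_calls = {s: het_calls[s] for s in samples}
    hom_calls = {s: hom_calls[s] for s in samples}
    all_het = [c for calls in het_calls.values() for c in calls]
    all_hom = [c for calls in hom_calls.values() for c in calls]

    # stage 3: copy number
    covs = [c for c in cohort.coverages if c.sample not in set(dropped)]
    cn = pd.Series(
        {c.sample: cn_mod.estimate_copy_number(c).copy_number for c in covs}
    ).loc[samples]
    nuclear = pd.Series({c.sample: c.nuclear_mean for c in covs}).loc[samples]

    # stage 4: annotation
    annotated_het = ann_mod.annotate(
        all_het, cohort.annotation, code, ref_seq,
        cohort.score_table, cohort.disease_catalog, cutoff=cadd_cutoff,
    )
    annotated_hom = ann_mod.annotate(
        all_hom, cohort.annotation, code, ref_seq,
        cohort.score_table, cohort.disease_catalog, cutoff=cadd_cutoff,
    )
    sweep = ann_mod.pathogenic_sweep(
        [v for v in annotated_het if v.effect == "nonsynonymous"],
        [v for v in annotated_hom if v.effect == "nonsynonymous"],
    )
    spectrum = maf_spectrum(all_het) if all_het else np.zeros(3)

    # stage 5: association battery
    phen = cohort.phenotypes[keep_mask].reset_index(drop=True)
    het_counts = np.array([len(het_calls[s]) for s in samples])
    models = assoc.age_models(het_counts, cn.to_numpy(), phen, nuclear.to_numpy())
    ages = pd.Series(phen["age"].to_numpy(), index=samples)
    group_table = assoc.group_summary(het_calls, ages)
    cat_table = assoc.category_summary_by_age(annotated_het, ages)
    trait_cols = [
        c for c in phen.columns if c not in ("sample", "age", "haplogroup")
    ]
    scan_cn = assoc.phenotype_scan(
        cn.to_numpy(), phen, phen["age"].to_numpy(), traits=trait_cols, fwer=fwer
    )
    hom_geno = _hom_genotype_frame(hom_calls, samples)
    hom_scan = assoc.homoplasmy_scan(
        cn.to_numpy(), hom_geno, phen["age"].to_numpy(), nuclear.to_numpy(), fwer=fwer
    )
    try:
        hap_scan = assoc.haplogroup_scan(
            het_counts, phen["haplogroup"],
            covariates=pd.DataFrame({"age": phen["age"].to_numpy()}),
        )
    except (ValueError, KeyError):
        hap_scan = None

    # stage 6: kernel association test over the log-transformed traits
    skat_df = _run_skat(
        cohort, samples, tables, het_calls, hom_geno, cn, phen,
        trait_cols if skat_traits is None else list(skat_traits), fwer, seed,
    )

    results = CohortResults(
        samples=samples,
        het_calls=het_calls,
        hom_calls=hom_calls,
        contamination=report_df,
        dropped=dropped,
        copy_numbers=cn,
        annotated_het=annotated_het,
        annotated_hom=annotated_hom,
        maf_spectrum=spectrum,
        age_models=models,
        group_table=group_table,
        category_table=cat_table,
        phenotype_scan_cn=scan_cn,
        homoplasmy_scan=hom_scan,
        haplogroup_scan_het=hap_scan,
        pathogenic_sweep=sweep,
        skat_results=skat_df,
        extras={"nuclear_coverage": nuclear},
    )
    if outdir is not None:
        _write_reports(results, cohort, Path(outdir))
    return results


def _hom_genotype_frame(hom_calls: dict, samples: list[str]) -> pd.DataFrame:
    variants = sorted(
        {(c.position, c.alt) for calls in hom_calls.values() for c in calls}
    )
    cols = {f"{pos}{alt}": np.zeros(len(samples)) for pos, alt in variants}
    index = {s: i for i, s in enumerate(samples)}
    for s, calls in hom_calls.items():
        for c in calls:
            cols[f"{c.position}{c.alt}"][index[s]] = 1.0
    return pd.DataFrame(cols, index=samples)


def _run_skat(
    cohort, samples, tables, het_calls, hom_geno, cn, phen, traits, fwer, seed
) -> pd.DataFrame:
    union_sites = sorted({(c.position, c.minor) for calls in het_calls.values() for c in calls})
    if not union_sites:
        return pd.DataFrame(columns=["trait", "mode", "Q", "p", "m", "significant"])
    # population-level polymorphisms: homoplasmic in > 1% of samples
    poly_positions = {
        int(v[:-1]) for v in hom_geno.columns if hom_geno[v].mean() > 0.01
    }
    exclude = {s for s in union_sites if s[0] in poly_positions}
    # covariates: age, copy number and 2 PCs of the homoplasmy matrix
    if hom_geno.shape[1] >= 2:
        pcs = skat_mod.pc_covariates(hom_geno.to_numpy(), k=2)
    else:
        pcs = np.zeros((len(samples), 0))
    C = np.column_stack([phen["age"].to_numpy(), cn.to_numpy(), pcs])
    rows = []
    for mode in ("maf", "binary"):
        X = skat_mod.build_het_matrix(
            tables, union_sites, mode=mode, exclude_polymorphic=exclude
        )
        weights = np.array(
            [
                _site_weight(cohort.score_table, cohort.ref_seq, pos, minor)
                for pos, minor in X.sites
            ]
        )
        alpha = assoc.bonferroni_alpha(len(traits), fwer)
        battery = skat_mod.KernelTestBattery(X, C, weights)
        for trait in traits:
            y = phen[trait].to_numpy(dtype=float)
            if np.any(y <= 0):
                continue
            res = battery.test(y, log_transform=True, response=trait)
            rows.append(
                {
                    "trait": trait,
                    "mode": mode,
                    "Q": res.q,
                    "p": res.p,
                    "m": res.m,
                    "significant": res.p < alpha,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)


def _site_weight(score_table, ref_seq, pos, minor):
    # the minor allele's score against the reference base; NaN when unscored
    ref = ref_seq[pos - 1].upper()
    val = score_table.lookup(pos, ref, minor)
    if val is None:
        # the call may sit on top of a homoplasmic substitution; try any alt
        for other in "ACGT":
            if other == minor:
                continue
            val = score_table.lookup(pos, other, minor)
            if val is not None:
                break
    return np.nan if val is None else val


def _write_reports(results: CohortResults, cohort, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    all_het = [c for calls in results.het_calls.values() for c in calls]
    all_hom = [c for calls in results.hom_calls.values() for c in calls]
    io_mod.write_heteroplasmy_csv(all_het, cohort.ref_seq, outdir / "heteroplasmies.csv")
    io_mod.write_homoplasmy_tsv(all_hom, outdir / "homoplasmies.tsv")
    results.contamination.to_csv(outdir / "contamination.tsv", sep="\t", index=False)
    results.copy_numbers.rename("copy_number").to_csv(
        outdir / "copy_number.tsv", sep="\t", index_label="sample"
    )
    results.group_table.to_csv(outdir / "age_groups.csv", index=False)
    results.category_table.to_csv(outdir / "age_group_categories.csv", index=False)
    results.phenotype_scan_cn.to_csv(outdir / "phenotype_scan_cn.tsv", sep="\t", index=False)
    results.homoplasmy_scan.to_csv(outdir / "homoplasmy_scan.tsv", sep="\t", index=False)
    if results.haplogroup_scan_het is not None:
        results.haplogroup_scan_het.to_csv(
            outdir / "haplogroup_scan.tsv", sep="\t", index=False
        )
    results.pathogenic_sweep.to_csv(outdir / "pathogenic_sweep.tsv", sep="\t", index=False)
    results.skat_results.to_csv(outdir / "skat.tsv", sep="\t", index=False)
    with open(outdir / "age_models.txt", "w") as fh:
        for name, model in results.age_models.items():
            fh.write(f"== {name} ==\n{model}\n\n")
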