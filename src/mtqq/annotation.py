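"""Variant annotation: region, coding effect, pathogenicity score, disease flag.

Pathogenic potential comes from a scaled CADD-like score table; a variant is
flagged pathogenic when its score reaches the cutoff (default 15, inclusive;
a sweep over 12..22 guards against the arbitrary choice).  Disease status is
a catalog lookup.  Spectrum summaries (length-normalised occurrence per
locus, score comparisons between MAF strata, the one-vs-rest chi-square
locus outlier test) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import HeteroplasmyCall, HomoplasmyCall
from .reference import GenomeAnnotation, GeneticCodeTable, coding_effect

__all__ = [
    "ScoreTable",
    "DiseaseCatalog",
    "AnnotatedVariant",
    "annotate",
    "unique_variants",
    "pathogenic_sweep",
    "score_group_comparison",
    "occurrence_by_locus",
    "locus_outlier_test",
]

DEFAULT_CADD_CUTOFF = 15.0


@dataclass
class ScoreTable:
    """(position, ref, alt) -> scaled pathogenicity score."""

    scores: dict[tuple[int, str, str], float]

    def lookup(self, pos: int, ref: str, alt: str) -> float | None:
        val = self.scores.get((pos, ref.upper(), alt.upper()))
        if val is not None and not np.isfinite(val):
            raise ValueError(f"non-finite score at {pos} {ref}>{alt}")
        return val

    @classmethod
    def read_tsv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                (int(r.position), str(r.ref).upper(), str(r.alt).upper()): float(
                    r.scaled_score
                )
                for r in df.itertuples(index=False)
            }
        )

    def write_tsv(self, path) -> None:
        rows = [
            {"position": p, "ref": r, "alt": a, "scaled_score": s}
            for (p, r, a), s in sorted(self.scores.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class DiseaseCatalog:
    """Set of (position, alt) disease-associated variants."""

    variants: set[tuple[int, str]]

    def __contains__(self, item: tuple[int, str]) -> bool:
        pos, alt = item
        return (pos, alt.upper()) in self.variants

    @classmethod
    def read_tsv(cls, path) -> "DiseaseCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls({(int(r.position), str(r.alt).upper()) for r in df.itertuples(index=False)})

    def write_tsv(self, path) -> None:
        rows = [{"position": p, "alt": a} for p, a in sorted(self.variants)]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnnotatedVariant:
    sample: str
    position: int
    ref: str  # allele on the reference/consensus side of the call
    alt: str  # the variant allele (minor allele for heteroplasmies)
    kind: str  # 'heteroplasmy' | 'homoplasmy'
    maf: float | None
    locus: str | None
    category: str
    effect: str
    score: float | None
    disease: bool
    pathogenic: bool | None  # None when the score is missing


def _call_alleles(call) -> tuple[str, str, float | None, str]:
    if isinstance(call, HeteroplasmyCall):
        return call.major, call.minor, call.maf, "heteroplasmy"
    if isinstance(call, HomoplasmyCall):
        return call.ref, call.alt, None, "homoplasmy"
    raise TypeError(f"unsupported call type {type(call).__name__}")


def annotate(
    calls,
    ann: GenomeAnnotation,
    code: GeneticCodeTable,
    ref_seq: str,
    scores: ScoreTable,
    diseases: DiseaseCatalog,
    cutoff: float = DEFAULT_CADD_CUTOFF,
) -> list[AnnotatedVariant]:
    """Annotate every call; missing scores leave the pathogenic flag absent
    (None) and are tallied in a warning."""
    out = []
    missing = 0
    for call in calls:
        ref, alt, maf, kind = _call_alleles(call)
        locus, category = ann.classify(call.position)
        if category == "protein_coding" and ref_seq[call.position - 1].upper() == ref:
            effect = coding_effect(ann, code, ref_seq, call.position, ref, alt)
        elif category == "protein_coding":
            # the call's major allele differs from the reference (e.g. a
            # heteroplasmy on top of a homoplasmic substitution): classify
            # the alt against the reference base instead
            base = ref_seq[call.position - 1].upper()
            effect = (
                coding_effect(ann, code, ref_seq, call.position, base, alt)
                if base != alt
                else "synonymous"
            )
        else:
            effect = "noncoding"
        score = scores.lookup(call.position, ref, alt)
        if score is None:
            missing += 1
        out.append(
            AnnotatedVariant(
                sample=call.sample,
                position=call.position,
                ref=ref,
                alt=alt,
                kind=kind,
                maf=maf,
                locus=locus,
                category=category,
                effect=effect,
                score=score,
                disease=(call.position, alt) in diseases,
                pathogenic=None if score is None else score >= cutoff,
            )
        )
    if missing:
        warnings.warn(
            f"{missing}/{len(out)} calls had no pathogenicity score", stacklevel=2
        )
    return out


def unique_variants(variants: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Deduplicate by (position, alt): a variant occurring in multiple
    individuals is counted once."""
    seen: dict[tuple[int, str], AnnotatedVariant] = {}
    for v in variants:
        seen.setdefault((v.position, v.alt), v)
    return list(seen.values())


def _pathogenic_fraction(scored: np.ndarray, cutoff: float) -> float:
    return float((scored >= cutoff).mean()) if scored.size else np.nan


def pathogenic_sweep(
    het_variants: list[AnnotatedVariant],
    hom_variants: list[AnnotatedVariant],
    cutoffs=range(12, 23),
) -> pd.DataFrame:
    """Pathogenic fraction per cutoff for unique nonsynonymous heteroplasmies
    vs homoplasmies, and their ratio (NaN when the denominator is 0)."""
    het_scores = np.array(
        [v.score for v in unique_variants(het_variants) if v.score is not None]
    )
    hom_scores = np.array(
        [v.score for v in unique_variants(hom_variants) if v.score is not None]
    )
    rows = []
    for cutoff in cutoffs:
        fh = _pathogenic_fraction(het_scores, cutoff)
        fm = _pathogenic_fraction(hom_scores, cutoff)
        ratio = fh / fm if fm and np.isfinite(fm) else np.nan
        rows.append(
            {"cutoff": cutoff, "het_fraction": fh, "hom_fraction": fm, "ratio": ratio}
        )
    return pd.DataFrame(rows)


def score_group_comparison(
    nonsyn_het: list[AnnotatedVariant],
    maf_cutoff: float = 0.10,
    sweep=(0.05, 0.06, 0.07, 0.08, 0.09),
) -> pd.DataFrame:
    """Welch two-sample t-test of pathogenicity scores, low-MAF vs high-MAF
    unique nonsynonymous heteroplasmies, at the primary cutoff and a sweep."""
    uniq = [
        v
        for v in unique_variants(nonsyn_het)
        if v.score is not None and v.maf is not None
    ]
    rows = []
    for cutoff in (maf_cutoff, *sweep):
        low = np.array([v.score for v in uniq if v.maf <= cutoff])
        high = np.array([v.score for v in uniq if v.maf > cutoff])
        if len(low) < 2 or len(high) < 2:
            warnings.warn(
                f"MAF cutoff {cutoff}: a group is too small, skipped", stacklevel=2
            )
            continue
        t, p = stats.ttest_ind(low, high, equal_var=False)
        rows.append(
            {
                "maf_cutoff": cutoff,
                "n_low": len(low),
                "n_high": len(high),
                "mean_low": float(low.mean()),
                "mean_high": float(high.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def occurrence_by_locus(
    variants: list[AnnotatedVariant], ann: GenomeAnnotation
) -> pd.DataFrame:
    """Per-locus variant count divided by locus length (per bp), computed on
    unique variants; intergenic positions pool into one pseudo-locus."""
    uniq = unique_variants(variants)
    counts: dict[str, int] = {}
    for v in uniq:
        key = v.locus if v.locus is not None else "intergenic"
        counts[key] = counts.get(key, 0) + 1
    lengths = {l.name: l.length for l in ann.loci}
    lengths["intergenic"] = ann.category_lengths()["intergenic"]
    categories = {l.name: l.category for l in ann.loci}
    categories["intergenic"] = "intergenic"
    rows = []
    for name, length in lengths.items():
        c = counts.get(name, 0)
        rows.append(
            {
                "locus": name,
                "category": categories[name],
                "length": length,
                "count": c,
                "per_bp": c / length if length else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("locus", ignore_index=True)


def locus_outlier_test(
    variants: list[AnnotatedVariant],
    ann: GenomeAnnotation,
    category: str,
) -> pd.DataFrame:
    """One-vs-rest chi-square goodness of fit within a locus category.

    For each locus, the unique-variant count in the locus vs the rest of the
    category is compared against a length-proportional expectation (1 df).
    When an expected count falls below 1 the exact binomial test is used
    instead and flagged.
    """
    table = occurrence_by_locus(variants, ann)
    sub = table[table.category == category]
    if len(sub) < 2:
        raise ValueError(f"category {category!r} has fewer than 2 loci")
    total_count = int(sub["count"].sum())
    total_len = int(sub["length"].sum())
    rows = []
    for _, r in sub.iterrows():
        exp_in = total_count * r["length"] / total_len
        exp_out = total_count - exp_in
        obs_in = int(r["count"])
        obs_out = total_count - obs_in
        if total_count == 0:
            stat, p, exact = 0.0, 1.0, False
        elif min(exp_in, exp_out) < 1:
            p = stats.binomtest(obs_in, total_count, r["length"] / total_len).pvalue
            stat, exact = np.nan, True
        else:
            stat = (obs_in - exp_in) ** 2 / exp_in + (obs_out - exp_out) ** 2 / exp_out
            p = float(stats.chi2.sf(stat, df=1))
            exact = False
        rows.append(
            {
                "locus": r["locus"],
                "count": obs_in,
                "expected": exp_in,
                "chi2": stat,
                "p": float(p),
                "exact_fallback": exact,
            }
        )
    return pd.DataFrame(rows)
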