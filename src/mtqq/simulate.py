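"""Synthetic cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes — a female-cohort age distribution (mean 55.5 y, SD 12.8 y, range
17.3-84.5 y), a heteroplasmy burden that rises with age (Poisson intensity
a0 + a1*age, a1 = 0.011/yr), a low-MAF-skewed heteroplasmy spectrum
(truncated Beta), an mtDNA copy number that declines with age
(-0.395 copies/yr) with positively skewed residuals (skewness ~1.55,
median ~188), mean mitochondrial coverage ~568x tied to copy number through
the coverage-ratio identity, and blood-trait couplings (+0.102 SD
bicarbonate and -0.116 SD WBC per SD of copy number; ApoB log-linear in the
score-weighted heteroplasmy load).  Ground truth for every planted quantity
is returned so each pipeline stage can be scored against it.

Sequencing is simulated at the allele-count level (no reads): per-site depth
is Poisson, allele counts are binomial in the allele fraction, strands split
1:1, and substitution errors arrive uniformly at ``per_base_error`` per read
base.  Cross-sample contamination is binomial mixing of two samples' counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import AlleleCountTable
from .copynumber import AUTOSOMES, CoverageSummary
from .annotation import DiseaseCatalog, ScoreTable
from .reference import (
    BASES,
    MT_LENGTH,
    GenomeAnnotation,
    HaplogroupTable,
    base_index,
    coding_effect,
    default_annotation,
    synthetic_reference,
    vertebrate_mito_code,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "mix_samples",
    "synthetic_haplogroup_table",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters; the defaults are the study conditions."""

    n_individuals: int = 1511
    seed: int = 0
    # age law: truncated normal
    age_mean: float = 55.5
    age_sd: float = 12.8
    age_range: tuple[float, float] = (17.3, 84.5)
    # heteroplasmy intensity: E[count | age] = het_baseline + het_age_slope * age
    het_baseline: float = 0.30
    het_age_slope: float = 0.011
    # MAF law: mixture of Beta(maf_alpha, maf_beta) truncated to
    # (maf_min, maf_max] and, with weight maf_tail_weight, a uniform tail on
    # the same support (low-MAF body plus the heavy high-MAF tail seen in
    # blood heteroplasmy spectra)
    maf_alpha: float = 1.2
    maf_beta: float = 55.0
    maf_tail_weight: float = 0.23
    maf_min: float = 0.02
    maf_max: float = 0.5
    # copy number: cn_intercept + cn_age_slope * age + Gamma(shape, scale)
    cn_intercept: float = 130.0
    cn_age_slope: float = -0.395
    cn_noise_shape: float = 1.664  # skewness 2/sqrt(shape) ~ 1.55
    cn_noise_scale: float = 58.8
    cn_floor: float = 10.0
    # sequencing
    nuclear_depth: float = 5.5
    nuclear_depth_sd: float = 0.4
    autosome_mean_cv: float = 0.01
    per_base_error: float = 2e-3
    # variant placement
    control_region_enrichment: float = 6.0
    disease_fraction: float = 0.14
    private_hom_rate: float = 2.0
    # phenotype couplings (per-SD standardized effects)
    bicarbonate_effect: float = 0.102
    wbc_effect: float = -0.116
    apob_effect: float = 0.40
    n_null_traits: int = 28
    # contamination mixtures
    contamination_pairs: int = 0
    contamination_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        lo, hi = self.age_range
        if not (0 < lo < hi < 120):
            raise ValueError("age_range must lie within (0, 120)")
        if not (0 < self.maf_min < self.maf_max <= 0.5):
            raise ValueError("MAF law support must lie within (0, 0.5]")
        for name in (
            "het_baseline", "het_age_slope", "per_base_error",
            "nuclear_depth", "cn_noise_shape", "cn_noise_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cn_floor <= 0 and self.cn_intercept + self.cn_age_slope * hi <= 0:
            raise ValueError(
                "copy-number model can reach non-positive values without a floor"
            )
        if self.contamination_pairs and not (0 < self.contamination_fraction < 0.5):
            raise ValueError("contamination fraction must lie in (0, 0.5)")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its ground truth."""

    config: CohortConfig
    ref_seq: str
    annotation: GenomeAnnotation
    haplogroups: HaplogroupTable
    tables: list[AlleleCountTable]
    coverages: list[CoverageSummary]
    phenotypes: pd.DataFrame
    truth_samples: pd.DataFrame  # sample, age, copy_number, haplogroup, ...
    truth_hets: pd.DataFrame  # sample, position, major, minor, true_maf, ...
    truth_homs: pd.DataFrame  # sample, position, ref, alt
    score_table: ScoreTable
    disease_catalog: DiseaseCatalog

    @property
    def samples(self) -> list[str]:
        return list(self.truth_samples["sample"])


def synthetic_haplogroup_table(
    ref_seq: str, n_groups: int = 10, seed: int = 20170913
) -> HaplogroupTable:
    """A synthetic stand-in haplogroup-defining-variant table.

    Ten lineages named after the common European mtDNA haplogroups, each
    defined by 12-18 homoplasmic substitutions at disjoint positions (so any
    two groups differ at >= 24 sites).  Deterministic given ``seed``;
    positions and alleles refer to the supplied reference.
    """
    names = ["H", "U", "K", "J", "T", "V", "W", "I", "X", "R"][:n_groups]
    rng = np.random.default_rng(seed)
    sizes = rng.integers(12, 19, size=len(names))
    pool = rng.choice(np.arange(200, len(ref_seq) - 200), size=sizes.sum() * 2, replace=False)
    pool_iter = iter(pool.tolist())
    groups: dict[str, set] = {}
    for name, size in zip(names, sizes):
        variants = set()
        while len(variants) < size:
            pos = next(pool_iter)
            ref = ref_seq[pos - 1].upper()
            alt = BASES[(base_index(ref) + int(rng.integers(1, 4))) % 4]
            variants.add((int(pos), ref, alt))
        groups[name] = variants
    return HaplogroupTable(groups, reference_name=names[0])


#: haplogroup frequencies of a predominantly European-descent female cohort
_HAPLOGROUP_FREQS = {
    "H": 0.485, "U": 0.146, "K": 0.095, "J": 0.089, "T": 0.083,
    "V": 0.030, "W": 0.025, "I": 0.020, "X": 0.015, "R": 0.012,
}


def _truncated_beta(rng, a, b, lo, hi, size):
    u = rng.uniform(size=size)
    flo, fhi = stats.beta.cdf([lo, hi], a, b)
    return stats.beta.ppf(flo + u * (fhi - flo), a, b)


def _draw_mafs(rng, config: CohortConfig, size: int) -> np.ndarray:
    """Minor-allele fractions from the body+tail mixture law."""
    body = _truncated_beta(
        rng, config.maf_alpha, config.maf_beta, config.maf_min, config.maf_max, size
    )
    tail = rng.uniform(config.maf_min, config.maf_max, size=size)
    use_tail = rng.uniform(size=size) < config.maf_tail_weight
    return np.where(use_tail, tail, body)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(size=size)
    flo, fhi = stats.norm.cdf([a, b])
    return mean + sd * stats.norm.ppf(flo + u * (fhi - flo))


def _site_weights(annotation: GenomeAnnotation, enrichment: float) -> np.ndarray:
    w = np.ones(annotation.genome_length)
    for locus in annotation.loci:
        if locus.category == "control_region":
            for s, e in locus.intervals:
                w[s - 1 : e] = enrichment
    return w / w.sum()


def _synthetic_disease_catalog(
    ref_seq: str, rng: np.random.Generator, n: int = 300
) -> set[tuple[int, str]]:
    positions = rng.choice(np.arange(1, len(ref_seq) + 1), size=n, replace=False)
    out = set()
    for pos in positions:
        ref = ref_seq[pos - 1].upper()
        alt = BASES[(base_index(ref) + int(rng.integers(1, 4))) % 4]
        out.add((int(pos), alt))
    return out


# score laws per coding effect as normal mixtures [(weight, mean, sd), ...].
# Pathogenicity scores are bimodal (a benign and a deleterious mode);
# heteroplasmies carry more mass in the deleterious mode than homoplasmies
# (purifying selection keeps deleterious alleles at low fraction), giving
# nonsynonymous means ~14.3 vs ~10.8 and above-cutoff fractions ~0.51 vs
# ~0.33 at the default cutoff of 15.
_HET_SCORE_LAW = {
    "nonsynonymous": [(0.6, 17.0, 2.0), (0.4, 10.3, 2.0)],
    "synonymous": [(1.0, 5.5, 3.0)],
    "stop_gain": [(1.0, 18.0, 4.0)],
    "stop_loss": [(1.0, 18.0, 4.0)],
    "noncoding": [(1.0, 8.0, 4.0)],
}
_HOM_SCORE_LAW = {
    "nonsynonymous": [(0.38, 17.3, 2.0), (0.62, 6.9, 2.0)],
    "synonymous": [(1.0, 4.5, 2.5)],
    "stop_gain": [(1.0, 12.0, 4.0)],
    "stop_loss": [(1.0, 12.0, 4.0)],
    "noncoding": [(1.0, 6.5, 3.5)],
}
_DISEASE_SCORE_LAW = [(1.0, 17.4, 4.0)]


#: deleterious-mode weight for nonsynonymous heteroplasmies by MAF stratum:
#: purifying selection keeps the most deleterious alleles at low fraction,
#: so low-MAF variants carry more mass in the high-score mode
_HET_NONSYN_DELETERIOUS_WEIGHT = {"low": 0.66, "high": 0.45}
_HET_NONSYN_MAF_BOUNDARY = 0.10


def _draw_from_law(rng: np.random.Generator, law) -> float:
    weights = np.array([w for w, _, _ in law])
    i = int(rng.choice(len(law), p=weights / weights.sum()))
    _, mu, sd = law[i]
    return float(max(rng.normal(mu, sd), 0.1))


def _sample_counts(
    rng: np.random.Generator,
    depth_mean: float,
    ref_codes: np.ndarray,
    hom_variants: list[tuple[int, int]],
    het_variants: list[tuple[int, int, float]],
    error_rate: float,
) -> np.ndarray:
    L = len(ref_codes)
    rows = np.arange(L)
    cons = ref_codes.copy()
    for pos, alt in hom_variants:
        cons[pos - 1] = alt
    # Poisson splitting: total depth ~ Poisson(depth_mean) multinomially
    # split over (base, strand) is equivalent to independent Poisson cells
    err = min(error_rate, 0.75)
    lam = np.full((L, 4), depth_mean * err / 3.0)
    lam[rows, cons] = depth_mean * (1.0 - err)
    counts = rng.poisson(np.broadcast_to(lam[:, :, None] / 2.0, (L, 4, 2))).astype(
        np.int32
    )
    for pos, alt, maf in het_variants:
        i = pos - 1
        d = int(counts[i].sum())
        minor = int(rng.binomial(d, maf))
        major = d - minor
        major_base = int(cons[i])
        counts[i] = 0
        mf = int(rng.binomial(minor, 0.5))
        Mf = int(rng.binomial(major, 0.5))
        counts[i, alt, 0], counts[i, alt, 1] = mf, minor - mf
        counts[i, major_base, 0] += Mf
        counts[i, major_base, 1] += major - Mf
    return counts


def simulate_cohort(
    config: CohortConfig,
    ref_seq: str | None = None,
    annotation: GenomeAnnotation | None = None,
    haplogroups: HaplogroupTable | None = None,
) -> SyntheticCohort:
    """Generate a full cohort; bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    ref_seq = ref_seq if ref_seq is not None else synthetic_reference()
    annotation = annotation if annotation is not None else default_annotation()
    haplogroups = (
        haplogroups if haplogroups is not None else synthetic_haplogroup_table(ref_seq)
    )
    code = vertebrate_mito_code()
    L = len(ref_seq)
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    ref_codes = lut[np.frombuffer(ref_seq.encode(), dtype=np.uint8)]
    n = config.n_individuals
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    # demographics and true per-sample quantities
    ages = _truncated_normal(
        rng, config.age_mean, config.age_sd, *config.age_range, size=n
    )
    cn_noise = rng.gamma(config.cn_noise_shape, config.cn_noise_scale, size=n)
    copy_number = np.maximum(
        config.cn_intercept + config.cn_age_slope * ages + cn_noise, config.cn_floor
    )
    nuclear_depth = np.clip(
        rng.normal(config.nuclear_depth, config.nuclear_depth_sd, size=n), 0.5, None
    )
    mt_depth = copy_number * nuclear_depth / 2.0  # the coverage-ratio identity

    # haplogroup assignment and homoplasmies
    names = [g for g in haplogroups.names if g in _HAPLOGROUP_FREQS] or haplogroups.names
    freqs = np.array([_HAPLOGROUP_FREQS.get(g, 0.01) for g in names])
    freqs = freqs / freqs.sum()
    hap_of = rng.choice(names, size=n, p=freqs)

    # disease catalog (deterministic per cohort seed via the same stream)
    disease = _synthetic_disease_catalog(ref_seq, rng)
    disease_list = sorted(disease)

    site_p = _site_weights(annotation, config.control_region_enrichment)

    # plant heteroplasmies (all draws batched, then split per sample)
    het_counts = rng.poisson(config.het_baseline + config.het_age_slope * ages)
    total_k = int(het_counts.sum())
    site_cdf = np.cumsum(site_p)
    all_mafs = _draw_mafs(rng, config, total_k)
    all_disease = rng.uniform(size=total_k) < config.disease_fraction
    all_positions = np.searchsorted(site_cdf, rng.uniform(size=total_k)) + 1
    disease_pick = rng.integers(len(disease_list), size=total_k)
    alt_offsets = rng.integers(1, 4, size=total_k)
    het_rows = []
    per_sample_hets: list[list[tuple[int, int, float]]] = []
    cursor = 0
    for i in range(n):
        k = int(het_counts[i])
        mine: list[tuple[int, int, float]] = []
        used = set()
        for j in range(cursor, cursor + k):
            if all_disease[j]:
                pos, alt_base = disease_list[disease_pick[j]]
                alt = base_index(alt_base)
                if alt == ref_codes[pos - 1]:
                    alt = (alt + 1) % 4
            else:
                pos = int(all_positions[j])
                alt = (int(ref_codes[pos - 1]) + int(alt_offsets[j])) % 4
            if pos in used:
                continue
            used.add(pos)
            mine.append((pos, alt, float(all_mafs[j])))
        cursor += k
        per_sample_hets.append(mine)
        for pos, alt, maf in mine:
            het_rows.append(
                {
                    "sample": sample_ids[i],
                    "position": pos,
                    "major": BASES[ref_codes[pos - 1]],
                    "minor": BASES[alt],
                    "true_maf": maf,
                    "disease": (pos, BASES[alt]) in disease,
                }
            )

    # homoplasmies: haplogroup defining variants + a few private ones
    hom_rows = []
    per_sample_homs: list[list[tuple[int, int]]] = []
    for i in range(n):
        defs = sorted(haplogroups.groups[hap_of[i]])
        mine = [(pos, base_index(alt)) for pos, _, alt in defs]
        for _ in range(int(rng.poisson(config.private_hom_rate))):
            pos = int(rng.integers(1, L + 1))
            if any(p == pos for p, _ in mine):
                continue
            alt = (int(ref_codes[pos - 1]) + int(rng.integers(1, 4))) % 4
            mine.append((pos, alt))
        het_positions = {p for p, _, _ in per_sample_hets[i]}
        mine = [(p, a) for p, a in mine if p not in het_positions]
        per_sample_homs.append(mine)
        for pos, alt in mine:
            hom_rows.append(
                {
                    "sample": sample_ids[i],
                    "position": pos,
                    "ref": BASES[ref_codes[pos - 1]],
                    "alt": BASES[alt],
                }
            )

    # pathogenicity scores for every planted variant
    scores: dict[tuple[int, str, str], float] = {}

    def _draw_score(pos, ref_b, alt_b, law_by_effect, maf=None):
        key = (pos, ref_b, alt_b)
        if key in scores:
            return scores[key]
        if (pos, alt_b) in disease:
            law = _DISEASE_SCORE_LAW
        else:
            _, category = annotation.classify(pos)
            if category == "protein_coding" and ref_seq[pos - 1].upper() == ref_b:
                effect = coding_effect(annotation, code, ref_seq, pos, ref_b, alt_b)
            elif category == "protein_coding":
                effect = "nonsynonymous"
            else:
                effect = "noncoding"
            law = law_by_effect[effect]
            if effect == "nonsynonymous" and maf is not None:
                stratum = "low" if maf <= _HET_NONSYN_MAF_BOUNDARY else "high"
                w = _HET_NONSYN_DELETERIOUS_WEIGHT[stratum]
                (_, hi_mu, hi_sd), (_, lo_mu, lo_sd) = _HET_SCORE_LAW["nonsynonymous"]
                law = [(w, hi_mu, hi_sd), (1 - w, lo_mu, lo_sd)]
        scores[key] = _draw_from_law(rng, law)
        return scores[key]

    for row in het_rows:
        row["score"] = _draw_score(
            row["position"], row["major"], row["minor"], _HET_SCORE_LAW,
            maf=row["true_maf"],
        )
    for row in hom_rows:
        _draw_score(row["position"], row["ref"], row["alt"], _HOM_SCORE_LAW)

    # phenotypes
    def _coupled(effect: float, z_driver: np.ndarray) -> np.ndarray:
        noise = rng.normal(size=n)
        return effect * z_driver + np.sqrt(max(1 - effect**2, 0.0)) * noise

    def _z(x):
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    z_cn = _z(copy_number)
    load = np.zeros(n)
    load_bin = np.zeros(n)
    for i in range(n):
        site_scores = [
            scores[(p, BASES[ref_codes[p - 1]], BASES[a])]
            for p, a, _ in per_sample_hets[i]
        ]
        load[i] = sum(
            s * m for s, (_, _, m) in zip(site_scores, per_sample_hets[i])
        )
        load_bin[i] = sum(site_scores)
    # ApoB is driven by the weighted burden through both its facets: the
    # minor-allele fractions and the plain heteroplasmic-site occupancy
    z_load = _z(_z(load) + _z(load_bin))
    bicarbonate = 26.0 + 2.65 * _coupled(config.bicarbonate_effect, z_cn)
    wbc = np.clip(7.0 + 2.0 * _coupled(config.wbc_effect, z_cn), 0.5, None)
    platelets = np.clip(rng.normal(250.0, 60.0, size=n), 10.0, None)
    apob = np.exp(
        np.log(1.0) + 0.25 * _coupled(config.apob_effect, z_load)
    )
    phen = {
        "sample": sample_ids,
        "age": ages,
        "haplogroup": hap_of,
        "wbc": wbc,
        "platelets": platelets,
        "bicarbonate": bicarbonate,
        "apob": apob,
    }
    for t in range(config.n_null_traits):
        phen[f"trait{t + 1:02d}"] = np.exp(rng.normal(0.0, 0.3, size=n))
    phenotypes = pd.DataFrame(phen)

    # sequencing: allele-count tables and coverage summaries
    tables, coverages = [], []
    for i in range(n):
        counts = _sample_counts(
            rng,
            mt_depth[i],
            ref_codes,
            per_sample_homs[i],
            per_sample_hets[i],
            config.per_base_error,
        )
        table = AlleleCountTable(sample_ids[i], counts)
        tables.append(table)
        wobble = 1.0 + config.autosome_mean_cv * rng.normal(size=len(AUTOSOMES))
        autosomal = {
            c: float(nuclear_depth[i] * w) for c, w in zip(AUTOSOMES, wobble)
        }
        mt_mean = float(table.depth_vector().mean())
        coverages.append(CoverageSummary(sample_ids[i], autosomal, mt_mean))

    # contamination mixtures
    contaminated = np.zeros(n, dtype=bool)
    partner = np.array([""] * n, dtype=object)
    if config.contamination_pairs:
        candidates = np.arange(n)
        rng.shuffle(candidates)
        made = 0
        used: set[int] = set()
        for a in candidates:
            if made >= config.contamination_pairs:
                break
            if a in used:
                continue
            others = [
                b for b in candidates
                if b != a and b not in used and hap_of[b] != hap_of[a]
            ]
            if not others:
                continue
            b = others[0]
            tables[a] = mix_samples(
                tables[a], tables[b], config.contamination_fraction, rng
            )
            contaminated[a] = True
            partner[a] = sample_ids[b]
            used.update((int(a), int(b)))
            made += 1

    truth_samples = pd.DataFrame(
        {
            "sample": sample_ids,
            "age": ages,
            "copy_number": copy_number,
            "nuclear_depth": nuclear_depth,
            "mt_depth": mt_depth,
            "haplogroup": hap_of,
            "het_count": het_counts,
            "het_load": load,
            "contaminated": contaminated,
            "partner": partner,
        }
    )
    het_cols = ["sample", "position", "major", "minor", "true_maf", "disease", "score"]
    hom_cols = ["sample", "position", "ref", "alt"]
    truth_hets = (
        pd.DataFrame(het_rows, columns=het_cols)
        if het_rows
        else pd.DataFrame(columns=het_cols)
    )
    truth_homs = (
        pd.DataFrame(hom_rows, columns=hom_cols)
        if hom_rows
        else pd.DataFrame(columns=hom_cols)
    )
    return SyntheticCohort(
        config=config,
        ref_seq=ref_seq,
        annotation=annotation,
        haplogroups=haplogroups,
        tables=tables,
        coverages=coverages,
        phenotypes=phenotypes,
        truth_samples=truth_samples,
        truth_hets=truth_hets,
        truth_homs=truth_homs,
        score_table=ScoreTable(scores),
        disease_catalog=DiseaseCatalog(disease),
    )


def mix_samples(
    a: AlleleCountTable,
    b: AlleleCountTable,
    fraction: float,
    seed: int | np.random.Generator = 0,
) -> AlleleCountTable:
    """Binomial cross-contamination: thin(a, 1-fraction) + thin(b, fraction).

    Total depth is approximately preserved; every cell keeps binomial
    sampling noise, the way a physical DNA mixture would.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    if a.genome_length != b.genome_length:
        raise ValueError("mismatched genome lengths")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mixed = rng.binomial(a.counts, 1.0 - fraction) + rng.binomial(b.counts, fraction)
    return AlleleCountTable(a.sample, mixed.astype(np.int64))
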