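"""mtDNA copy number from WGS coverage ratios.

A diploid cell carries two copies of each autosome, so the ratio of mean
mitochondrial to mean autosomal sequencing coverage estimates mtDNA copies
per cell:

    copy_number = 2 * mean(MT coverage) / mean_{i=1..22}(autosome_i coverage)

The autosomal aggregate is the unweighted mean of the 22 per-contig mean
depths (not a length-weighted genome mean).  The upstream read-filter
contract for real alignments — mapping quality > 20, duplicates removed,
< 5 mismatches — is an ingestion precondition, not re-checked here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AUTOSOMES",
    "CoverageSummary",
    "CopyNumberEstimate",
    "summarize_coverage",
    "estimate_copy_number",
    "describe_distribution",
]

AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class CoverageSummary:
    """Per-contig mean depths for autosomes 1..22 plus MT."""

    sample: str
    autosomal: dict[str, float]
    mt: float

    def __post_init__(self) -> None:
        missing = [c for c in AUTOSOMES if c not in self.autosomal]
        if missing:
            raise ValueError(f"missing autosomal contigs: {', '.join(missing)}")
        extra = set(self.autosomal) - set(AUTOSOMES)
        if extra:
            raise ValueError(f"unexpected contigs: {sorted(extra)}")
        if self.mt < 0 or any(v < 0 for v in self.autosomal.values()):
            raise ValueError("negative mean coverage")

    @property
    def nuclear_mean(self) -> float:
        """Unweighted mean of the 22 autosomal mean depths."""
        return float(np.mean([self.autosomal[c] for c in AUTOSOMES]))


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample: str
    copy_number: float


def summarize_coverage(
    sample: str, per_site_depths: dict[str, np.ndarray]
) -> CoverageSummary:
    """Arithmetic mean over all sites of each contig (zero-depth sites count)."""
    missing = [c for c in (*AUTOSOMES, "MT") if c not in per_site_depths]
    if missing:
        raise ValueError(f"missing contigs: {', '.join(missing)}")
    means = {}
    for contig, depths in per_site_depths.items():
        depths = np.asarray(depths)
        if depths.size == 0:
            raise ValueError(f"contig {contig} has no sites")
        means[contig] = float(depths.mean())
    mt = means.pop("MT")
    return CoverageSummary(sample, means, mt)


def estimate_copy_number(cov: CoverageSummary) -> CopyNumberEstimate:
    """2 x MT mean / unweighted autosomal mean; scale-invariant."""
    nuclear = cov.nuclear_mean
    if nuclear <= 0:
        raise ValueError(f"sample {cov.sample}: nuclear mean coverage is zero")
    return CopyNumberEstimate(cov.sample, 2.0 * cov.mt / nuclear)


def describe_distribution(estimates) -> dict:
    """Cohort descriptives: mean, median, min, max, adjusted Fisher-Pearson
    skewness and the D'Agostino skewness-test p-value.

    With fewer than 8 samples the test is omitted (descriptives only); for
    constant data the skewness is undefined and reported as such.
    """
    values = np.array(
        [e.copy_number if isinstance(e, CopyNumberEstimate) else float(e) for e in estimates]
    )
    if values.size == 0:
        raise ValueError("no copy-number estimates")
    out = {
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "skewness": None,
        "skew_test_p": None,
    }
    if np.ptp(values) == 0:
        warnings.warn("constant copy numbers: skewness undefined", stacklevel=2)
        return out
    out["skewness"] = float(stats.skew(values, bias=False))
    if values.size >= 8:
        out["skew_test_p"] = float(stats.skewtest(values).pvalue)
    else:
        warnings.warn(
            "fewer than 8 samples: D'Agostino skewness test omitted", stacklevel=2
        )
    return out
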