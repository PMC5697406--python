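"""Heteroplasmy and homoplasmy calling from quality-filtered allele counts.

The caller's sole input is an :class:`AlleleCountTable`: per position, per
base, per strand read counts that survived the base-quality filter (phred >=
20 at ingestion).  A site is called heteroplasmic when

* sequencing depth is strictly greater than 200,
* the minor (second-most-frequent) allele reaches a frequency of at least 2%,
* and the minor allele is seen at least twice on each strand.

Homoplasmies are consensus substitutions: the consensus base differs from the
reference and carries >= 98% of reads (1 - min_maf).  Indels are out of
scope; calls are substitutions only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import BASES, MT_LENGTH

__all__ = [
    "AlleleCountTable",
    "CallCriteria",
    "HeteroplasmyCall",
    "HomoplasmyCall",
    "call_heteroplasmies",
    "call_homoplasmies",
    "downsample",
    "maf_spectrum",
    "consensus_sequence",
]

STRANDS = ("fwd", "rev")


@dataclass
class AlleleCountTable:
    """Per-position, per-base, per-strand quality-filtered read counts.

    ``counts`` has shape (genome_length, 4, 2): bases in A<C<G<T order,
    strands (fwd, rev).  Position ``p`` (1-based) lives at ``counts[p-1]``.
    """

    sample: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[1:] != (4, 2):
            raise ValueError("counts must have shape (genome_length, 4, 2)")
        if np.issubdtype(self.counts.dtype, np.floating):
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative allele counts")

    @property
    def genome_length(self) -> int:
        return self.counts.shape[0]

    def depth(self, pos: int) -> int:
        return int(self.counts[pos - 1].sum())

    def depth_vector(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def total_bases(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def empty(cls, sample: str, genome_length: int = MT_LENGTH) -> "AlleleCountTable":
        return cls(sample, np.zeros((genome_length, 4, 2), dtype=np.int64))


@dataclass(frozen=True)
class CallCriteria:
    """Heteroplasmy thresholds.  Depth is strict (>); MAF and per-strand
    minor counts are inclusive (>=)."""

    min_depth: int = 200
    min_maf: float = 0.02
    min_minor_per_strand: int = 2
    min_base_quality: int = 20  # applied at ingestion, recorded here

    def __post_init__(self) -> None:
        if not 0 < self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in (0, 0.5]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass(frozen=True)
class HeteroplasmyCall:
    sample: str
    position: int
    major: str
    minor: str
    maf: float
    depth: int
    minor_fwd: int
    minor_rev: int


@dataclass(frozen=True)
class HomoplasmyCall:
    sample: str
    position: int
    ref: str
    alt: str
    alt_fraction: float
    depth: int


def _major_minor(totals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position indices of the most and second-most frequent base.

    Ties break by the fixed base order A<C<G<T (argmax returns the first
    maximum).
    """
    major = totals.argmax(axis=1)
    masked = totals.copy()
    masked[np.arange(len(totals)), major] = -1
    minor = masked.argmax(axis=1)
    return major, minor


def call_heteroplasmies(
    table: AlleleCountTable, crit: CallCriteria = CallCriteria()
) -> list[HeteroplasmyCall]:
    """Apply the three heteroplasmy criteria to every position."""
    totals = table.counts.sum(axis=2)  # (L, 4)
    depth = totals.sum(axis=1)
    major, minor = _major_minor(totals)
    rows = np.arange(len(totals))
    minor_total = totals[rows, minor]
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(depth > 0, minor_total / np.maximum(depth, 1), 0.0)
    minor_fwd = table.counts[rows, minor, 0]
    minor_rev = table.counts[rows, minor, 1]
    ok = (
        (depth > crit.min_depth)
        & (maf >= crit.min_maf)
        & (minor_fwd >= crit.min_minor_per_strand)
        & (minor_rev >= crit.min_minor_per_strand)
    )
    return [
        HeteroplasmyCall(
            sample=table.sample,
            position=int(i + 1),
            major=BASES[major[i]],
            minor=BASES[minor[i]],
            maf=float(maf[i]),
            depth=int(depth[i]),
            minor_fwd=int(minor_fwd[i]),
            minor_rev=int(minor_rev[i]),
        )
        for i in np.flatnonzero(ok)
    ]


def call_homoplasmies(
    table: AlleleCountTable,
    crit: CallCriteria,
    ref_seq: str,
) -> list[HomoplasmyCall]:
    """Consensus substitutions: consensus != reference at >= 1 - min_maf."""
    totals = table.counts.sum(axis=2)
    depth = totals.sum(axis=1)
    consensus = totals.argmax(axis=1)
    rows = np.arange(len(totals))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, totals[rows, consensus] / np.maximum(depth, 1), 0.0)
    ref_idx = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    ref_codes = lut[ref_idx]
    ok = (
        (depth > crit.min_depth)
        & (frac >= 1.0 - crit.min_maf)
        & (consensus != ref_codes)
        & (ref_codes >= 0)
    )
    return [
        HomoplasmyCall(
            sample=table.sample,
            position=int(i + 1),
            ref=BASES[ref_codes[i]],
            alt=BASES[consensus[i]],
            alt_fraction=float(frac[i]),
            depth=int(depth[i]),
        )
        for i in np.flatnonzero(ok)
    ]


def downsample(
    table: AlleleCountTable,
    target_reads: int = 60_000,
    read_length: int = 100,
    seed: int | np.random.Generator = 0,
) -> AlleleCountTable:
    """Binomially thin counts to ~``target_reads`` reads of ``read_length`` bp.

    Every cell is thinned with p = target base total / current base total, so
    the expected post-thinning mean coverage is target_reads * read_length /
    genome_length (~362x for 60,000 reads of 100 bp).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    current = table.total_bases()
    target = target_reads * read_length
    if target > current:
        raise ValueError(
            f"target base total {target} exceeds current total {current}"
        )
    p = target / current
    if p == 1.0:
        return replace(table, counts=table.counts.copy())
    thinned = rng.binomial(table.counts, p)
    return AlleleCountTable(table.sample, thinned.astype(np.int64))


DEFAULT_MAF_BINS = (0.0, 0.05, 0.10, 0.5000001)
DEFAULT_MAF_BIN_LABELS = ("<5%", "5-10%", ">10%")


def maf_spectrum(
    calls: list[HeteroplasmyCall],
    bin_edges: tuple[float, ...] = DEFAULT_MAF_BINS,
) -> np.ndarray:
    """Proportion of calls per MAF bin; bins are [lo, hi) on the edges given.

    Default report bins: <5%, 5-10%, >10%.
    """
    if not calls:
        warnings.warn("maf_spectrum of an empty call set", stacklevel=2)
        return np.zeros(len(bin_edges) - 1)
    mafs = np.array([c.maf for c in calls])
    counts, _ = np.histogram(mafs, bins=np.asarray(bin_edges))
    return counts / len(calls)


def consensus_sequence(
    table: AlleleCountTable,
    calls: list[HeteroplasmyCall],
    ref_seq: str,
    which: str = "major",
    min_depth: int = 0,
) -> set[tuple[int, str]]:
    """Variant set of a sample consensus vs the reference.

    ``which='major'``: the consensus base at every covered position.
    ``which='minor_at_het_sites'``: the same, except the minor base is
    substituted at each heteroplasmic site.  Returned as {(pos, alt)}
    differences from the reference; homoplasmic substitutions appear in both.
    """
    if which not in ("major", "minor_at_het_sites"):
        raise ValueError(f"unknown consensus mode {which!r}")
    totals = table.counts.sum(axis=2)
    depth = totals.sum(axis=1)
    consensus = totals.argmax(axis=1)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    ref_codes = lut[np.frombuffer(ref_seq.encode(), dtype=np.uint8)]
    mismatch = np.flatnonzero(
        (depth > min_depth) & (consensus != ref_codes) & (ref_codes >= 0)
    )
    out: set[tuple[int, str]] = {(int(i + 1), BASES[consensus[i]]) for i in mismatch}
    if which == "minor_at_het_sites":
        for call in calls:
            out.discard((call.position, call.major))
            if ref_seq[call.position - 1].upper() != call.minor:
                out.add((call.position, call.minor))
    return out
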