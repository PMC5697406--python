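"""Cross-sample contamination screening.

A sample is flagged as contaminated only when two independent signals agree:

1. its heteroplasmy count is an outlier for the cohort (strictly above
   Q3 + 1.5 * IQR, linear-interpolation quartiles), and
2. the consensus sequences built from its major alleles and from its minor
   alleles at heteroplasmic sites assign to *different* haplogroups.

The count threshold is always derived from the cohort at hand — a cohort
whose quartiles imply a threshold of 8 will suspect samples with more than 8
heteroplasmies, but 8 is never hard-coded.  Haplogroup assignment is a flat
defining-variant matcher (fraction of a haplogroup's defining variants
present), which is all the same-vs-different decision needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import AlleleCountTable, CallCriteria, HeteroplasmyCall, consensus_sequence
from .reference import HaplogroupTable

__all__ = [
    "ContaminationReport",
    "iqr_threshold",
    "assign_haplogroup",
    "screen_cohort",
]


@dataclass(frozen=True)
class ContaminationReport:
    sample: str
    het_count: int
    threshold: float
    outlier: bool
    major_haplogroup: str
    minor_haplogroup: str
    contaminated: bool


def iqr_threshold(het_counts, multiplier: float = 1.5) -> float:
    """Q3 + multiplier * (Q3 - Q1) with linear-interpolation quantiles;
    counts strictly greater are outliers."""
    counts = np.asarray(het_counts, dtype=float)
    if counts.size < 4:
        raise ValueError("need at least 4 samples for quartile estimation")
    q1, q3 = np.percentile(counts, [25, 75])
    return float(q3 + multiplier * (q3 - q1))


def assign_haplogroup(
    variants: set[tuple[int, str]], table: HaplogroupTable
) -> tuple[str, float]:
    """Best-matching haplogroup for a variant set {(pos, alt)}.

    Score = matched defining variants / defining variants; ties break by more
    absolute matches, then lexicographic name.  An empty variant set returns
    the reference haplogroup with score 0.
    """
    if not table.groups:
        raise ValueError("empty haplogroup table")
    if not variants:
        return table.reference_name, 0.0
    best = None
    for name in sorted(table.groups):
        defs = {(pos, alt) for pos, _, alt in table.groups[name]}
        matched = len(defs & variants)
        score = matched / len(defs) if defs else 0.0
        key = (score, matched, [-ord(c) for c in name])
        if best is None or key > best[0]:
            best = (key, name, score)
    return best[1], float(best[2])


def screen_cohort(
    tables: list[AlleleCountTable],
    calls_per_sample: dict[str, list[HeteroplasmyCall]],
    haplogroups: HaplogroupTable,
    ref_seq: str,
    crit: CallCriteria = CallCriteria(),
    multiplier: float = 1.5,
    require_both: bool = True,
) -> list[ContaminationReport]:
    """Apply the two-criterion rule to every sample.

    ``require_both=False`` relaxes the conjunction to the count criterion
    alone (for sensitivity analyses).
    """
    counts = [len(calls_per_sample.get(t.sample, [])) for t in tables]
    threshold = iqr_threshold(counts, multiplier=multiplier)
    reports = []
    for table, het_count in zip(tables, counts):
        calls = calls_per_sample.get(table.sample, [])
        outlier = het_count > threshold
        major = consensus_sequence(table, calls, ref_seq, "major", crit.min_depth)
        minor = consensus_sequence(
            table, calls, ref_seq, "minor_at_het_sites", crit.min_depth
        )
        hap_major, _ = assign_haplogroup(major, haplogroups)
        hap_minor, _ = assign_haplogroup(minor, haplogroups)
        discordant = hap_major != hap_minor
        contaminated = (outlier and discordant) if require_both else outlier
        reports.append(
            ContaminationReport(
                sample=table.sample,
                het_count=het_count,
                threshold=threshold,
                outlier=outlier,
                major_haplogroup=hap_major,
                minor_haplogroup=hap_minor,
                contaminated=contaminated,
            )
        )
    return reports


def reports_to_frame(reports: list[ContaminationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
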