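"""Readers and writers for the external formats.

Allele counts travel either as the six-column pileup dialect (chrom, pos,
ref, depth, bases, qualities; strand inferred from character case, qualities
phred+33, base-quality filter applied on read) or as a long-format count TSV
(sample, pos, base, strand, count).  Heteroplasmy calls are written as a CSV
with the schema (sample, pos, ref, major, minor, MAF, depth, minor_fwd,
minor_rev).  All text is UTF-8 with '.' decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import AlleleCountTable, CallCriteria, HeteroplasmyCall, HomoplasmyCall
from .copynumber import AUTOSOMES, CoverageSummary
from .reference import BASES, MT_LENGTH, base_index

__all__ = [
    "read_pileup",
    "write_pileup",
    "read_count_tsv",
    "write_count_tsv",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "write_heteroplasmy_csv",
    "read_heteroplasmy_csv",
    "write_homoplasmy_tsv",
    "PipelineConfig",
]


class PileupError(ValueError):
    pass


def _parse_base_column(
    bases: str, quals: str, ref: str, min_quality: int, lineno: int
) -> np.ndarray:
    """One pileup base string -> (4, 2) counts, quality-filtered."""
    out = np.zeros((4, 2), dtype=np.int64)
    ref = ref.upper()
    i = q = 0
    nb = len(bases)
    while i < nb:
        c = bases[i]
        if c == "^":
            i += 2  # mapping-quality character follows
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            start = i
            while i < nb and bases[i].isdigit():
                i += 1
            if start == i:
                raise PileupError(f"line {lineno}: malformed indel token")
            i += int(bases[start:i])  # skip inserted/deleted sequence
            continue
        # a real base column consumes one quality character
        if q >= len(quals):
            raise PileupError(f"line {lineno}: quality string shorter than bases")
        quality = ord(quals[q]) - 33
        q += 1
        i += 1
        if c in "*><":
            continue  # deletion placeholder / reference skip
        if c == ".":
            base, strand = ref, 0
        elif c == ",":
            base, strand = ref, 1
        elif c.upper() in BASES:
            base, strand = c.upper(), 0 if c.isupper() else 1
        elif c in "Nn":
            continue
        else:
            raise PileupError(f"line {lineno}: unexpected pileup character {c!r}")
        if quality >= min_quality:
            out[base_index(base), strand] += 1
    if q != len(quals):
        raise PileupError(f"line {lineno}: quality string longer than bases")
    return out


def read_pileup(
    path,
    sample: str | None = None,
    min_base_quality: int = 20,
    genome_length: int = MT_LENGTH,
) -> AlleleCountTable:
    """Read the six-column pileup dialect into an AlleleCountTable."""
    counts = np.zeros((genome_length, 4, 2), dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PileupError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            _, pos_s, ref, depth_s, bases, quals = fields[:6]
            try:
                pos = int(pos_s)
                int(depth_s)
            except ValueError as exc:
                raise PileupError(f"line {lineno}: bad position/depth") from exc
            if not 1 <= pos <= genome_length:
                raise PileupError(f"line {lineno}: position {pos} out of range")
            counts[pos - 1] += _parse_base_column(
                bases, quals, ref, min_base_quality, lineno
            )
    return AlleleCountTable(sample or Path(path).stem, counts)


def write_pileup(
    table: AlleleCountTable, ref_seq: str, path, chrom: str = "chrM", quality_char: str = "I"
) -> None:
    """Emit covered positions as pileup lines (all bases at phred 40)."""
    with open(path, "w") as fh:
        for i in range(table.genome_length):
            cell = table.counts[i]
            depth = int(cell.sum())
            if depth == 0:
                continue
            ref = ref_seq[i].upper()
            parts = []
            for b in range(4):
                base = BASES[b]
                fwd, rev = int(cell[b, 0]), int(cell[b, 1])
                if base == ref:
                    parts.append("." * fwd + "," * rev)
                else:
                    parts.append(base * fwd + base.lower() * rev)
            bases = "".join(parts)
            fh.write(
                f"{chrom}\t{i + 1}\t{ref}\t{depth}\t{bases}\t{quality_char * depth}\n"
            )


def write_count_tsv(table: AlleleCountTable, path) -> None:
    """Long-format counts: sample, pos, base, strand, count (nonzero cells)."""
    pos_idx, base_idx, strand_idx = np.nonzero(table.counts)
    df = pd.DataFrame(
        {
            "sample": table.sample,
            "pos": pos_idx + 1,
            "base": [BASES[b] for b in base_idx],
            "strand": ["fwd" if s == 0 else "rev" for s in strand_idx],
            "count": table.counts[pos_idx, base_idx, strand_idx],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_tsv(path, genome_length: int = MT_LENGTH) -> AlleleCountTable:
    df = pd.read_csv(path, sep="\t")
    counts = np.zeros((genome_length, 4, 2), dtype=np.int64)
    sample = str(df["sample"].iloc[0]) if len(df) else Path(path).stem
    for row in df.itertuples(index=False):
        strand = 0 if str(row.strand) == "fwd" else 1
        counts[int(row.pos) - 1, base_index(str(row.base)), strand] += int(row.count)
    return AlleleCountTable(sample, counts)


def write_coverage_tsv(summaries: list[CoverageSummary], path) -> None:
    rows = []
    for s in summaries:
        for contig in AUTOSOMES:
            rows.append({"sample": s.sample, "contig": contig, "mean_depth": s.autosomal[contig]})
        rows.append({"sample": s.sample, "contig": "MT", "mean_depth": s.mt})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path) -> list[CoverageSummary]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sample, sub in df.groupby("sample", sort=False):
        means = dict(zip(sub["contig"].astype(str), sub["mean_depth"].astype(float)))
        mt = means.pop("MT", None)
        if mt is None:
            raise ValueError(f"sample {sample}: no MT row in {path}")
        out.append(CoverageSummary(str(sample), means, mt))
    return out


_HET_COLUMNS = [
    "sample", "pos", "ref", "major", "minor", "MAF", "depth", "minor_fwd", "minor_rev",
]


def write_heteroplasmy_csv(
    calls: list[HeteroplasmyCall], ref_seq: str, path
) -> None:
    rows = [
        {
            "sample": c.sample,
            "pos": c.position,
            "ref": ref_seq[c.position - 1].upper(),
            "major": c.major,
            "minor": c.minor,
            "MAF": c.maf,
            "depth": c.depth,
            "minor_fwd": c.minor_fwd,
            "minor_rev": c.minor_rev,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_HET_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_heteroplasmy_csv(path) -> list[HeteroplasmyCall]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        HeteroplasmyCall(
            sample=str(r.sample),
            position=int(r.pos),
            major=str(r.major),
            minor=str(r.minor),
            maf=float(r.MAF),
            depth=int(r.depth),
            minor_fwd=int(r.minor_fwd),
            minor_rev=int(r.minor_rev),
        )
        for r in df.itertuples(index=False)
    ]


def write_homoplasmy_tsv(calls: list[HomoplasmyCall], path) -> None:
    rows = [
        {
            "sample": c.sample,
            "pos": c.position,
            "ref": c.ref,
            "alt": c.alt,
            "alt_fraction": c.alt_fraction,
            "depth": c.depth,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["sample", "pos", "ref", "alt", "alt_fraction", "depth"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run, loadable from YAML."""

    reference_fasta: str | None = None
    gene_map_bed: str | None = None
    score_tsv: str | None = None
    disease_tsv: str | None = None
    haplogroup_tsv: str | None = None
    phenotype_tsv: str | None = None
    criteria: CallCriteria = field(default_factory=CallCriteria)
    cadd_cutoff: float = 15.0
    fwer: float = 0.05
    contamination_multiplier: float = 1.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        crit = CallCriteria(**raw.pop("criteria", {}))
        return cls(criteria=crit, **raw)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if k != "criteria"}
        data["criteria"] = {
            "min_depth": self.criteria.min_depth,
            "min_maf": self.criteria.min_maf,
            "min_minor_per_strand": self.criteria.min_minor_per_strand,
            "min_base_quality": self.criteria.min_base_quality,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
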