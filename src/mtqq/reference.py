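"""Mitochondrial coordinate system, gene map, genetic code and haplogroup tables.

Everything downstream (calling, annotation, association) consults this module
for the 16,569 bp mitochondrial genome: which locus a position belongs to,
whether a substitution is synonymous under the vertebrate mitochondrial code,
and which (near-)homoplasmic variants define each mtDNA haplogroup.

Coordinates are 1-based inclusive throughout (the convention of mtDNA variant
nomenclature); BED input is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

MT_LENGTH = 16569

#: single-label priority when loci overlap (each variant gets exactly one class)
CATEGORY_PRIORITY = ("protein_coding", "tRNA", "rRNA", "control_region")
CATEGORIES = CATEGORY_PRIORITY + ("intergenic",)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def base_index(base: str) -> int:
    """Index of a base in the fixed A<C<G<T order."""
    return _BASE_INDEX[base.upper()]


@dataclass(frozen=True)
class Locus:
    name: str
    intervals: tuple[tuple[int, int], ...]  # 1-based inclusive
    strand: str  # '+' or '-'
    category: str

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)


@dataclass
class GenomeAnnotation:
    """A gene map over the circular mitochondrial genome.

    Positions covered by no locus are intergenic.  A locus may own two
    intervals: the control region spans the origin and is represented as one
    locus with intervals (16024, 16569) and (1, 576).
    """

    loci: list[Locus]
    genome_length: int = MT_LENGTH
    _category_of: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for locus in self.loci:
            for s, e in locus.intervals:
                if not (1 <= s <= e <= self.genome_length):
                    raise ValueError(
                        f"locus {locus.name!r}: interval ({s},{e}) outside "
                        f"1..{self.genome_length}"
                    )
        self._warn_overlaps()
        # per-position single-label category (priority resolved), cached
        cat = np.full(self.genome_length + 1, len(CATEGORIES) - 1, dtype=np.int8)
        for rank in range(len(CATEGORY_PRIORITY) - 1, -1, -1):
            name = CATEGORY_PRIORITY[rank]
            for locus in self.loci:
                if locus.category != name:
                    continue
                for s, e in locus.intervals:
                    cat[s : e + 1] = rank
        self._category_of = cat

    def _warn_overlaps(self) -> None:
        coding = [l for l in self.loci if l.category == "protein_coding"]
        for i, a in enumerate(coding):
            for b in coding[i + 1 :]:
                if a.strand != b.strand:
                    continue
                for s1, e1 in a.intervals:
                    for s2, e2 in b.intervals:
                        if s1 <= e2 and s2 <= e1:
                            warnings.warn(
                                f"overlapping protein-coding loci on the same "
                                f"strand: {a.name} and {b.name}",
                                stacklevel=3,
                            )

    def loci_at(self, pos: int) -> list[Locus]:
        self._check_pos(pos)
        return [l for l in self.loci if l.contains(pos)]

    def classify(self, pos: int) -> tuple[str | None, str]:
        """Single-label (locus name, category) at ``pos``.

        Overlaps resolve by protein_coding > tRNA > rRNA > control_region;
        uncovered positions are (None, "intergenic").
        """
        hits = self.loci_at(pos)
        if not hits:
            return None, "intergenic"
        best = min(hits, key=lambda l: CATEGORY_PRIORITY.index(l.category))
        return best.name, best.category

    def category_lengths(self) -> dict[str, int]:
        """bp per single-label category; values sum to genome_length."""
        counts = np.bincount(
            self._category_of[1:], minlength=len(CATEGORIES)
        )
        return {name: int(counts[i]) for i, name in enumerate(CATEGORIES)}

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= self.genome_length:
            raise ValueError(f"position {pos} outside 1..{self.genome_length}")


def classify_position(ann: GenomeAnnotation, pos: int) -> tuple[str | None, str]:
    return ann.classify(pos)


# --- the standard rCRS gene map -------------------------------------------------

# (name, start, end, strand, category); 1-based inclusive rCRS coordinates.
_RCRS_LOCI: list[tuple[str, int, int, str, str]] = [
    ("TF", 577, 647, "+", "tRNA"),
    ("RNR1", 648, 1601, "+", "rRNA"),
    ("TV", 1602, 1670, "+", "tRNA"),
    ("RNR2", 1671, 3229, "+", "rRNA"),
    ("TL1", 3230, 3304, "+", "tRNA"),
    ("ND1", 3307, 4262, "+", "protein_coding"),
    ("TI", 4263, 4331, "+", "tRNA"),
    ("TQ", 4329, 4400, "-", "tRNA"),
    ("TM", 4402, 4469, "+", "tRNA"),
    ("ND2", 4470, 5511, "+", "protein_coding"),
    ("TW", 5512, 5579, "+", "tRNA"),
    ("TA", 5587, 5655, "-", "tRNA"),
    ("TN", 5657, 5729, "-", "tRNA"),
    ("TC", 5761, 5826, "-", "tRNA"),
    ("TY", 5826, 5891, "-", "tRNA"),
    ("CO1", 5904, 7445, "+", "protein_coding"),
    ("TS1", 7446, 7514, "-", "tRNA"),
    ("TD", 7518, 7585, "+", "tRNA"),
    ("CO2", 7586, 8269, "+", "protein_coding"),
    ("TK", 8295, 8364, "+", "tRNA"),
    ("ATP8", 8366, 8572, "+", "protein_coding"),
    ("ATP6", 8527, 9207, "+", "protein_coding"),
    ("CO3", 9207, 9990, "+", "protein_coding"),
    ("TG", 9991, 10058, "+", "tRNA"),
    ("ND3", 10059, 10404, "+", "protein_coding"),
    ("TR", 10405, 10469, "+", "tRNA"),
    ("ND4L", 10470, 10766, "+", "protein_coding"),
    ("ND4", 10760, 12137, "+", "protein_coding"),
    ("TH", 12138, 12206, "+", "tRNA"),
    ("TS2", 12207, 12265, "+", "tRNA"),
    ("TL2", 12266, 12336, "+", "tRNA"),
    ("ND5", 12337, 14148, "+", "protein_coding"),
    ("ND6", 14149, 14673, "-", "protein_coding"),
    ("TE", 14674, 14742, "-", "tRNA"),
    ("CYB", 14747, 15887, "+", "protein_coding"),
    ("TT", 15888, 15953, "+", "tRNA"),
    ("TP", 15956, 16023, "-", "tRNA"),
]


def default_annotation() -> GenomeAnnotation:
    """The standard rCRS gene map: 13 protein-coding genes, 22 tRNAs, 2 rRNAs
    and the origin-spanning control region (16024-16569 joined with 1-576)."""
    loci = [
        Locus(name, ((s, e),), strand, cat) for name, s, e, strand, cat in _RCRS_LOCI
    ]
    loci.append(Locus("CR", ((16024, 16569), (1, 576)), "+", "control_region"))
    with warnings.catch_warnings():
        # mtDNA has genuinely overlapping genes (ATP8/ATP6, ND4L/ND4)
        warnings.simplefilter("ignore")
        return GenomeAnnotation(loci)


def load_annotation(path, genome_length: int = MT_LENGTH) -> GenomeAnnotation:
    """Read a gene map from BED (0-based half-open -> 1-based inclusive).

    Expected columns: chrom, start, end, name, strand, category.  Two BED
    lines sharing a name become one locus with two intervals (the way an
    origin-spanning control region is written).
    """
    records: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=6 BED columns, "
                    f"got {len(fields)}"
                )
            _, start, end, name, strand, category = fields[:6]
            try:
                interval = (int(start) + 1, int(end))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates") from exc
            if category not in CATEGORIES:
                raise ValueError(
                    f"{path}: line {lineno}: unknown category {category!r}"
                )
            rec = records.setdefault(
                name, {"intervals": [], "strand": strand, "category": category}
            )
            rec["intervals"].append(interval)
    loci = [
        Locus(name, tuple(rec["intervals"]), rec["strand"], rec["category"])
        for name, rec in records.items()
    ]
    return GenomeAnnotation(loci, genome_length=genome_length)


# --- genetic code ---------------------------------------------------------------


@dataclass(frozen=True)
class GeneticCodeTable:
    """Vertebrate mitochondrial codon table (64 codons, stops marked '*')."""

    table: dict[str, str]

    def translate(self, codon: str) -> str:
        return self.table[codon.upper()]

    @property
    def stop_codons(self) -> set[str]:
        return {c for c, aa in self.table.items() if aa == "*"}


def vertebrate_mito_code() -> GeneticCodeTable:
    bio = CodonTable.unambiguous_dna_by_id[2]
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = "*"
    assert len(table) == 64
    return GeneticCodeTable(table)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def coding_effect(
    ann: GenomeAnnotation,
    code: GeneticCodeTable,
    ref_seq: str,
    pos: int,
    ref_base: str,
    alt_base: str,
) -> str:
    """Effect of a substitution: synonymous / nonsynonymous / stop_gain /
    stop_loss / noncoding.

    The codon is extracted from the reading frame of the protein-coding locus
    containing ``pos``; minus-strand loci are reverse-complemented before
    translation.  ``ref_base`` must match the reference sequence at ``pos``.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise ValueError("ref and alt bases are identical")
    if ref_seq[pos - 1].upper() != ref_base:
        raise ValueError(
            f"ref base {ref_base} does not match reference "
            f"{ref_seq[pos - 1].upper()} at position {pos}"
        )
    hits = [l for l in ann.loci_at(pos) if l.category == "protein_coding"]
    if not hits:
        return "noncoding"
    locus = hits[0]
    start, end = locus.intervals[0]
    if locus.strand == "+":
        offset = pos - start
        cds = ref_seq[start - 1 : end].upper()
        codon_i, in_codon = divmod(offset, 3)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt = alt_base
    else:
        offset = end - pos
        cds = ref_seq[start - 1 : end].upper()[::-1].translate(_COMPLEMENT)
        codon_i, in_codon = divmod(offset, 3)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt = alt_base.translate(_COMPLEMENT)
    if len(codon) < 3:
        warnings.warn(
            f"position {pos} falls in a partial terminal codon of {locus.name}; "
            "classified noncoding",
            stacklevel=2,
        )
        return "noncoding"
    mutant = codon[:in_codon] + alt + codon[in_codon + 1 :]
    aa_ref, aa_alt = code.translate(codon), code.translate(mutant)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*":
        return "stop_loss"
    return "nonsynonymous"


# --- haplogroup defining variants ----------------------------------------------


@dataclass
class HaplogroupTable:
    """Haplogroup name -> set of defining variants (pos, ref, alt)."""

    groups: dict[str, set[tuple[int, str, str]]]
    reference_name: str = "H"

    def __post_init__(self) -> None:
        for name, variants in self.groups.items():
            for pos, _, _ in variants:
                if not 1 <= pos <= MT_LENGTH:
                    raise ValueError(
                        f"haplogroup {name}: position {pos} out of range"
                    )

    @property
    def names(self) -> list[str]:
        return sorted(self.groups)


def load_haplogroup_table(path, reference_name: str = "H") -> HaplogroupTable:
    """TSV with columns: haplogroup, position, ref, alt."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    groups: dict[str, set] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(str(row.haplogroup), set()).add(
            (int(row.position), str(row.ref).upper(), str(row.alt).upper())
        )
    return HaplogroupTable(groups, reference_name=reference_name)


def write_haplogroup_table(table: HaplogroupTable, path) -> None:
    import pandas as pd

    rows = [
        {"haplogroup": name, "position": pos, "ref": ref, "alt": alt}
        for name, variants in sorted(table.groups.items())
        for pos, ref, alt in sorted(variants)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- reference sequence ---------------------------------------------------------


def load_reference(path) -> str:
    """First record of a FASTA file, upper-cased."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_reference(seq: str, path, name: str = "MT") -> None:
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


def synthetic_reference(seed: int = 7, length: int = MT_LENGTH) -> str:
    """A synthetic stand-in mitochondrial reference sequence.

    Deterministic given ``seed``; GC content ~44% (mtDNA-like).  Used whenever
    no user FASTA is supplied — all shipped coordinates refer to loci, not to
    particular reference bases, so analyses are internally consistent.
    """
    rng = np.random.default_rng(seed)
    probs = np.array([0.31, 0.31, 0.13, 0.25])  # A, C, G, T (heavy-strand-like)
    idx = rng.choice(4, size=length, p=probs)
    return "".join(BASES[i] for i in idx)
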