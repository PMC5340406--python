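"""Coding-consequence annotation of variants against transcript models.

Projects a genomic variant onto the spliced CDS of a transcript, classifies
the coding effect (synonymous / missense / nonsense / frameshift /
inframe_indel / intronic / intergenic / non_coding) and emits coding-DNA and
protein notation in the simplified single-letter HGVS dialect used in
veterinary genetics tables, e.g. ``c.31C>T`` / ``p.R11*`` for a nonsense
substitution in codon 11, or ``c.233delC`` / ``p.A78fs`` for a 1-bp
frameshifting deletion.

Conventions: transcript exon coordinates are 1-based inclusive genomic
intervals; CDS offsets are 1-based positions into the spliced coding-strand
sequence; the standard nuclear codon table is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "VariantRecord",
    "Consequence",
    "ReferenceMismatchError",
    "cds_position",
    "cds_to_genomic",
    "annotate_consequence",
    "annotate_best",
    "truncation_stats",
    "translate_cds",
    "EFFECT_SEVERITY",
]

STOP = "*"

#: severity ranking used when one variant hits several transcripts; higher is
#: more severe.
EFFECT_SEVERITY = {
    "nonsense": 6,
    "frameshift": 5,
    "missense": 4,
    "inframe_indel": 3,
    "synonymous": 2,
    "intronic": 1,
    "non_coding": 1,
    "intergenic": 0,
}

PROTEIN_CHANGING = frozenset({"missense", "nonsense", "frameshift"})
CODING_CLASSES = frozenset({"synonymous", "missense", "nonsense", "frameshift", "inframe_indel"})


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the transcript sequence."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a coding sequence up to (and excluding) the first stop codon."""
    aa = str(Seq(cds[: 3 * (len(cds) // 3)]).translate())
    stop = aa.find(STOP)
    return aa if stop < 0 else aa[:stop]


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript: exon structure plus its spliced CDS.

    Exons are genomic intervals (1-based, inclusive, sorted by genomic
    coordinate, non-overlapping) that here correspond exactly to the coding
    portion of each exon; ``cds_sequence`` is the spliced coding sequence on
    the coding strand (minus-strand transcripts store the reverse complement
    of the genome).
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.id}: exon start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")
            prev_end = end
        span = sum(e - s + 1 for s, e in self.exons)
        if span != len(self.cds_sequence):
            raise ValueError(
                f"{self.id}: exon span {span} != CDS length {len(self.cds_sequence)}"
            )
        if len(self.cds_sequence) % 3:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")
        if not self.cds_sequence.startswith("ATG"):
            raise ValueError(f"{self.id}: CDS does not start with ATG")
        last = str(Seq(self.cds_sequence[-3:]).translate())
        if last != STOP:
            raise ValueError(f"{self.id}: CDS does not end with a stop codon")

    @property
    def cds_start(self) -> int:
        """Leftmost genomic CDS coordinate."""
        return self.exons[0][0]

    @property
    def cds_end(self) -> int:
        """Rightmost genomic CDS coordinate."""
        return self.exons[-1][1]

    @property
    def n_residues(self) -> int:
        """Length of the full-length translation product (stop excluded)."""
        return len(self.cds_sequence) // 3 - 1


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant in VCF-style coordinates (1-based, explicit REF/ALT)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> str:
        return self.id or f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """Last reference base touched (1-based inclusive)."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class Consequence:
    """Classified coding effect of one variant on one transcript."""

    transcript: str
    effect_class: str
    cdna_notation: str = ""
    protein_notation: str = ""
    codon_index: int | None = None

    @property
    def is_protein_changing(self) -> bool:
        return self.effect_class in PROTEIN_CHANGING


def cds_position(variant: VariantRecord, transcript: TranscriptModel) -> int | None:
    """1-based offset of ``variant.pos`` into the spliced CDS, or None.

    Strand-aware: on minus-strand transcripts the offset counts from the
    genomic CDS end (the transcript 5' end). Returns None for intronic /
    intergenic positions.
    """
    if variant.chrom != transcript.chrom:
        return None
    return _genomic_to_cds(variant.pos, transcript)


def _genomic_to_cds(pos: int, transcript: TranscriptModel) -> int | None:
    offset = 0  # spliced bases strictly before the containing exon, genomic order
    for start, end in transcript.exons:
        if start <= pos <= end:
            plus_offset = offset + (pos - start + 1)
            if transcript.strand == "+":
                return plus_offset
            return len(transcript.cds_sequence) - plus_offset + 1
        offset += end - start + 1
    return None


def cds_to_genomic(cds_pos: int, transcript: TranscriptModel) -> int:
    """Genomic coordinate of the 1-based spliced CDS offset (inverse mapping)."""
    n = len(transcript.cds_sequence)
    if not 1 <= cds_pos <= n:
        raise ValueError(f"CDS position {cds_pos} outside 1..{n}")
    plus_offset = cds_pos if transcript.strand == "+" else n - cds_pos + 1
    for start, end in transcript.exons:
        exon_len = end - start + 1
        if plus_offset <= exon_len:
            return start + plus_offset - 1
        plus_offset -= exon_len
    raise AssertionError("unreachable: offset exceeded exon span")


def _locate(variant: VariantRecord, transcript: TranscriptModel) -> str:
    """Coarse location for non-CDS variants: intronic vs intergenic."""
    if variant.chrom != transcript.chrom:
        return "intergenic"
    if transcript.cds_start <= variant.pos <= transcript.cds_end:
        return "intronic"
    return "intergenic"


def _trim(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Trim shared prefix then shared suffix (left-normalised input assumed)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


def annotate_consequence(
    variant: VariantRecord, transcript: TranscriptModel
) -> Consequence:
    """Classify one variant against one transcript and build its notation.

    SNVs are classified by mutating the affected codon and translating ref
    and alt codons; indels by frame effect. The REF allele is checked against
    the transcript sequence and a :class:`ReferenceMismatchError` is raised
    on disagreement. Indels that extend outside the spliced CDS (splice /
    exon-boundary events) are classified ``non_coding`` and excluded from
    the protein-changing set.
    """
    if variant.is_snv:
        return _annotate_snv(variant, transcript)
    ref, alt, pos = _trim(variant.ref, variant.alt, variant.pos)
    if len(ref) == 1 and len(alt) == 1:
        return _annotate_snv(VariantRecord(variant.chrom, pos, ref, alt, variant.id), transcript)
    return _annotate_indel(variant, VariantRecord(variant.chrom, pos, ref, alt, variant.id), transcript)


def _annotate_snv(variant: VariantRecord, transcript: TranscriptModel) -> Consequence:
    p = cds_position(variant, transcript)
    if p is None:
        return Consequence(transcript.id, _locate(variant, transcript))
    cds = transcript.cds_sequence
    if transcript.strand == "+":
        cref, calt = variant.ref, variant.alt
    else:
        cref, calt = _revcomp(variant.ref), _revcomp(variant.alt)
    if cds[p - 1] != cref:
        raise ReferenceMismatchError(
            f"{transcript.id} CDS position {p}: transcript has {cds[p - 1]!r}, "
            f"variant REF implies {cref!r}"
        )
    ci = math.ceil(p / 3)
    codon = cds[3 * (ci - 1) : 3 * ci]
    within = (p - 1) % 3
    alt_codon = codon[:within] + calt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    cdna = f"c.{p}{cref}>{calt}"
    if alt_aa == STOP and ref_aa != STOP:
        return Consequence(transcript.id, "nonsense", cdna, f"p.{ref_aa}{ci}*", ci)
    if alt_aa == ref_aa:
        return Consequence(transcript.id, "synonymous", cdna, f"p.{ref_aa}{ci}=", ci)
    return Consequence(transcript.id, "missense", cdna, f"p.{ref_aa}{ci}{alt_aa}", ci)


def _annotate_indel(
    original: VariantRecord, variant: VariantRecord, transcript: TranscriptModel
) -> Consequence:
    ref, alt = variant.ref, variant.alt
    if len(ref) > len(alt) and ref.startswith(alt):
        # deletion: bases after the shared anchor are removed
        deleted = ref[len(alt) :]
        first_del = variant.pos + len(alt)
        offsets = [_genomic_to_cds(first_del + i, transcript) for i in range(len(deleted))]
        if any(o is None for o in offsets):
            return Consequence(transcript.id, "non_coding")
        p = min(offsets)  # type: ignore[type-var]
        cds_deleted = deleted if transcript.strand == "+" else _revcomp(deleted)
        k = len(deleted)
        cdna = f"c.{p}del{cds_deleted}" if k == 1 else f"c.{p}_{p + k - 1}del"
        ci = math.ceil(p / 3)
        ref_aa = str(Seq(transcript.cds_sequence[3 * (ci - 1) : 3 * ci]).translate())
        if k % 3:
            return Consequence(transcript.id, "frameshift", cdna, f"p.{ref_aa}{ci}fs", ci)
        return Consequence(transcript.id, "inframe_indel", cdna, f"p.{ref_aa}{ci}del", ci)
    if len(alt) > len(ref) and alt.startswith(ref):
        # insertion after the anchor base
        inserted = alt[len(ref) :]
        anchor = variant.pos + len(ref) - 1
        p = _genomic_to_cds(anchor, transcript)
        nxt = _genomic_to_cds(anchor + 1, transcript)
        if p is None or nxt is None:
            return Consequence(transcript.id, "non_coding")
        lo, hi = sorted((p, nxt))
        cds_ins = inserted if transcript.strand == "+" else _revcomp(inserted)
        cdna = f"c.{lo}_{hi}ins{cds_ins}"
        ci = math.ceil(lo / 3)
        ref_aa = str(Seq(transcript.cds_sequence[3 * (ci - 1) : 3 * ci]).translate())
        if len(inserted) % 3:
            return Consequence(transcript.id, "frameshift", cdna, f"p.{ref_aa}{ci}fs", ci)
        return Consequence(transcript.id, "inframe_indel", cdna, f"p.{ref_aa}{ci}ins", ci)
    # complex substitution (MNV): classify conservatively as non-coding/other
    return Consequence(transcript.id, "non_coding")


def annotate_best(
    variant: VariantRecord, transcripts: list[TranscriptModel]
) -> Consequence:
    """Most severe consequence of a variant across a transcript set.

    Variants overlapping no transcript at all are ``intergenic``.
    """
    best: Consequence | None = None
    for tx in transcripts:
        if tx.chrom != variant.chrom:
            continue
        cons = annotate_consequence(variant, tx)
        if best is None or EFFECT_SEVERITY[cons.effect_class] > EFFECT_SEVERITY[best.effect_class]:
            best = cons
    return best if best is not None else Consequence("", "intergenic")


def truncation_stats(
    consequence: Consequence, transcript: TranscriptModel
) -> tuple[int, int, float]:
    """(retained_residues, full_length_residues, retained_fraction) for a nonsense variant.

    A premature stop at codon *k* leaves the first *k* - 1 residues of the
    product; the full-length count excludes the natural stop.
    """
    if consequence.effect_class != "nonsense":
        raise ValueError(
            f"truncation_stats requires a nonsense consequence, got {consequence.effect_class!r}"
        )
    assert consequence.codon_index is not None
    retained = consequence.codon_index - 1
    full = transcript.n_residues
    return retained, full, retained / full
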