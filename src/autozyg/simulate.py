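"""Synthetic cohort generator for end-to-end testing of autozygosity mapping.

Emulates, at reduced genomic scale, the data of a recessive-disease mapping
study in a dog breed: a small multi-contig reference with protein-coding
gene models (one designated anillin-like transcript whose codon 11 is CGA),
a pedigree of affected siblings with obligate-carrier parent and
grandparent, SNP-array genotypes in which the cases share a planted
homozygous haplotype over one interval, and cohort/control variant calls
containing background variants, class-specific decoys, and one planted
causal nonsense substitution (a C>T at spliced CDS position 31) inside the
shared interval. The control panel never carries the causal allele.

Cohort counts default to study scale (7 cases, 5 close relatives, 176
population dogs of whom 3 carriers, 136 panel genomes) while the genome is
shrunk to 3 x 10 Mb; all randomness flows from a single master seed through
fixed per-component streams, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .consequence import TranscriptModel, VariantRecord, cds_to_genomic
from .filtering import CohortGenotypes
from .roh import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from .segregation import SampleInfo, SampleSheet

__all__ = [
    "SimConfig",
    "SimTruth",
    "ReferenceBundle",
    "SimBundle",
    "SizingError",
    "build_reference",
    "simulate_array_genotypes",
    "simulate_variant_cohort",
    "simulate_bundle",
]

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOPS
)

# fixed offsets for per-component random streams derived from the master seed
_STREAM_REFERENCE, _STREAM_ARRAY, _STREAM_COHORT = 11, 13, 17


class SizingError(ValueError):
    """A contig is too short for the requested gene content."""


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_contigs: int = 3
    contig_length_bp: int = 10_000_000
    n_array_snps_per_contig: int = 3_000
    n_genes: int = 8
    planted_roh: tuple[str, int, int] = ("chr1", 4_000_000, 6_000_000)
    causal_spec: tuple[int, int, str, str] = (0, 31, "C", "T")
    designated_n_residues: int = 1121
    n_cases: int = 7
    relative_roles: tuple[str, ...] = (
        "parent",
        "grandparent",
        "sibling",
        "sibling",
        "sibling",
    )
    n_population_controls: int = 176
    n_panel_controls: int = 136
    n_population_carriers: int = 3
    background_variant_rate: float = 2e-4
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_contigs", "contig_length_bp", "n_array_snps_per_contig",
                     "n_cases", "n_population_controls", "n_panel_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0 or self.n_population_carriers < 0:
            raise ValueError("n_genes and n_population_carriers must be >= 0")
        for name in ("background_variant_rate", "genotyping_error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        chrom, start, end = self.planted_roh
        if chrom not in self.contig_names:
            raise ValueError(f"planted ROH contig {chrom!r} does not exist")
        if not 1 <= start < end <= self.contig_length_bp:
            raise ValueError("planted ROH must lie within its contig")
        gi, cds_pos, ref, alt = self.causal_spec
        if self.n_genes and not 0 <= gi < self.n_genes:
            raise ValueError("causal gene index out of range")
        if cds_pos < 1 or cds_pos > 3 * self.designated_n_residues:
            raise ValueError("causal CDS position outside the designated CDS")
        if ref == alt or len(ref) != 1 or len(alt) != 1:
            raise ValueError("causal ref/alt must be distinct single bases")
        if self.n_population_carriers > self.n_population_controls:
            raise ValueError("more carriers than population controls")

    @property
    def contig_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_contigs))

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(f"case{i + 1}" for i in range(self.n_cases))

    @property
    def relative_ids(self) -> tuple[str, ...]:
        counts: dict[str, int] = {}
        out = []
        for role in self.relative_roles:
            counts[role] = counts.get(role, 0) + 1
            out.append(role if self.relative_roles.count(role) == 1 else f"{role}{counts[role]}")
        return tuple(out)


@dataclass
class SimTruth:
    """Ground truth emitted alongside synthetic data."""

    causal_variant_id: str = ""
    planted_roh_intervals_per_case: dict[str, list[tuple[str, int, int]]] = field(
        default_factory=dict
    )
    sample_roles: dict[str, str] = field(default_factory=dict)
    decoy_ids: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ReferenceBundle:
    """Contig sequences plus transcript models; the designated transcript
    carries the plantable causal codon."""

    contigs: dict[str, str]
    transcripts: list[TranscriptModel]
    designated_id: str
    config: SimConfig

    @property
    def designated(self) -> TranscriptModel:
        return next(t for t in self.transcripts if t.id == self.designated_id)


@dataclass
class SimBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    reference: ReferenceBundle
    array: GenotypeMatrix
    cohort: CohortGenotypes
    sheet: SampleSheet
    truth: SimTruth


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed % (2**31)])


def _random_sequence(rng: np.random.Generator, n: int) -> bytearray:
    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return bytearray(base_codes[rng.integers(0, 4, size=n)].tobytes())


def _make_cds(rng: np.random.Generator, n_residues: int, fixed: dict[int, str] | None = None) -> str:
    """Random complete CDS: ATG, ``n_residues - 1`` random sense codons, one stop.

    ``fixed`` pins specific codons by 1-based codon index.
    """
    codons = ["ATG"] + [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_residues - 1)]
    for idx, codon in (fixed or {}).items():
        codons[idx - 1] = codon
    codons.append("TAA")
    return "".join(codons)


@dataclass
class _GenePlan:
    index: int
    contig: str
    start: int
    strand: str
    n_residues: int
    n_exons: int


_INTRON_BP = 500
_GENE_SPACER_BP = 50_000


def _plan_genes(config: SimConfig, rng: np.random.Generator) -> list[_GenePlan]:
    roh_chrom, roh_start, roh_end = config.planted_roh
    gi = config.causal_spec[0]
    plans: list[_GenePlan] = []
    # keep ROH genes interior to the interval: window-based detection has
    # marker-scale slop at segment edges
    cursor_roh = roh_start + (roh_end - roh_start) // 4
    cursors = {c: 10_000 for c in config.contig_names}
    # genes outside the ROH on the planted contig start after the interval
    cursors[roh_chrom] = roh_end + 100_000
    minus_assigned = False
    for i in range(config.n_genes):
        if i == gi:
            n_res, n_ex, strand = config.designated_n_residues, 2, "+"
        else:
            n_res = int(rng.integers(100, 301))
            n_ex = int(rng.integers(1, 4))
            strand = "-" if not minus_assigned else ("+" if rng.random() < 0.5 else "-")
            if strand == "-":
                minus_assigned = True
        span = 3 * n_res + 3 + _INTRON_BP * (n_ex - 1)
        in_roh = i == gi or (i == (gi + 1) % max(config.n_genes, 1) and config.n_genes > 1)
        if in_roh:
            start = cursor_roh
            cursor_roh += span + _GENE_SPACER_BP
            if cursor_roh > roh_end:
                raise SizingError("planted ROH too short for its gene content")
            contig = roh_chrom
        else:
            contig = config.contig_names[i % config.n_contigs]
            start = cursors[contig]
            cursors[contig] += span + _GENE_SPACER_BP
            if start + span > config.contig_length_bp - 1_000:
                raise SizingError(f"contig {contig} too short for requested genes")
        plans.append(_GenePlan(i, contig, start, strand, n_res, n_ex))
    return plans


def _split_exons(start: int, cds_len: int, n_exons: int, first_exon_len: int | None) -> tuple[tuple[int, int], ...]:
    if first_exon_len is None:
        base = cds_len // n_exons
        lens = [base] * n_exons
        lens[-1] += cds_len - base * n_exons
    else:
        lens = [first_exon_len, cds_len - first_exon_len]
    exons = []
    pos = start
    for ln in lens:
        exons.append((pos, pos + ln - 1))
        pos += ln + _INTRON_BP
    return tuple(exons)


def build_reference(config: SimConfig) -> ReferenceBundle:
    """Build contig sequences and embedded transcript models.

    The designated transcript (gene index from ``causal_spec``) is a
    plus-strand two-exon gene whose spliced CDS encodes
    ``designated_n_residues`` residues with codon 11 fixed to CGA, so that a
    C>T at CDS position 31 creates a premature TGA stop. At least one other
    gene is placed on the minus strand, and (when there are >= 2 genes) one
    extra gene falls inside the planted ROH to host decoy variants.
    """
    rng = _rng(config, _STREAM_REFERENCE)
    seqs = {name: _random_sequence(rng, config.contig_length_bp) for name in config.contig_names}
    transcripts: list[TranscriptModel] = []
    gi, cds_pos, causal_ref, _ = config.causal_spec
    causal_codon_index = math.ceil(cds_pos / 3)
    if config.n_genes:
        for plan in _plan_genes(config, rng):
            fixed = {causal_codon_index: "CGA"} if plan.index == gi else None
            cds = _make_cds(rng, plan.n_residues, fixed)
            if plan.index == gi and cds[cds_pos - 1] != causal_ref:
                raise ValueError(
                    f"designated CDS base at {cds_pos} is {cds[cds_pos - 1]}, "
                    f"causal_spec expects {causal_ref}"
                )
            first_exon = 30 if plan.index == gi else None
            exons = _split_exons(plan.start, len(cds), plan.n_exons if plan.index != gi else 2, first_exon)
            genomic = cds if plan.strand == "+" else str(Seq(cds).reverse_complement())
            seq = seqs[plan.contig]
            offset = 0
            for s, e in exons:
                seq[s - 1 : e] = genomic[offset : offset + e - s + 1].encode()
                offset += e - s + 1
            transcripts.append(
                TranscriptModel(
                    id=f"tx{plan.index}",
                    chrom=plan.contig,
                    strand=plan.strand,
                    exons=exons,
                    cds_sequence=cds,
                    gene=f"gene{plan.index}",
                )
            )
    contigs = {name: seq.decode() for name, seq in seqs.items()}
    designated = f"tx{gi}" if config.n_genes else ""
    return ReferenceBundle(contigs, transcripts, designated, config)


def _sorted_unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while pos.size < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _array_sample_ids(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    """Array plate: cases, close relatives and a handful of population dogs."""
    n_pop = min(6, config.n_population_controls)
    ids = list(config.case_ids) + list(config.relative_ids) + [f"pop{i+1}" for i in range(n_pop)]
    roles = {s: "case" for s in config.case_ids}
    for s, role in zip(config.relative_ids, config.relative_roles):
        roles[s] = "obligate_carrier" if role in ("parent", "grandparent") else "unaffected_sib"
    for i in range(n_pop):
        roles[f"pop{i+1}"] = "population"
    return ids, roles


def simulate_array_genotypes(
    reference: ReferenceBundle, config: SimConfig, min_segment_snps: int = 100
) -> tuple[GenotypeMatrix, SimTruth]:
    """SNP-array genotypes with a planted shared homozygous haplotype.

    Markers get allele-B frequencies ~ U(0.05, 0.5) and Hardy-Weinberg
    genotypes; inside the planted interval the cases, the parent and the
    grandparent are all homozygous for one shared haplotype. Genotyping
    error (a call replaced by a random different call) and missingness are
    applied at the configured rates afterwards, so the planted signal
    degrades realistically.
    """
    rng = _rng(config, _STREAM_ARRAY)
    samples, roles = _array_sample_ids(config)
    hap_cols = [
        i for i, s in enumerate(samples)
        if roles[s] in ("case", "obligate_carrier")
    ]
    chroms_l, pos_l, fa_l, fb_l, ids_l, calls_l = [], [], [], [], [], []
    roh_chrom, roh_start, roh_end = config.planted_roh
    n_in_roh = 0
    for contig in config.contig_names:
        m = config.n_array_snps_per_contig
        pos = _sorted_unique_positions(rng, m, config.contig_length_bp)
        freq = rng.uniform(0.05, 0.5, size=m)
        calls = rng.binomial(2, freq[:, None], size=(m, len(samples))).astype(np.int8)
        if contig == roh_chrom:
            inside = (pos >= roh_start) & (pos <= roh_end)
            n_in_roh = int(inside.sum())
            hap = (rng.random(n_in_roh) < freq[inside]).astype(np.int8) * 2
            for c in hap_cols:
                calls[inside, c] = hap
        alleles = np.array(list("ACGT"))
        a_idx = rng.integers(0, 4, size=m)
        b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
        chroms_l.append(np.full(m, contig, dtype=object))
        pos_l.append(pos)
        fa_l.append(alleles[a_idx])
        fb_l.append(alleles[b_idx])
        ids_l.append(np.array([f"{contig}_snp{i}" for i in range(m)], dtype=object))
        calls_l.append(calls)
    calls = np.concatenate(calls_l, axis=0)

    if config.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate, MISSING, calls).astype(np.int8)

    matrix = GenotypeMatrix(
        np.concatenate(chroms_l),
        np.concatenate(pos_l),
        np.concatenate(fa_l),
        np.concatenate(fb_l),
        np.concatenate(ids_l),
        samples,
        calls,
    )
    truth = SimTruth(
        planted_roh_intervals_per_case={c: [config.planted_roh] for c in config.case_ids},
        sample_roles=roles,
    )
    if n_in_roh < min_segment_snps:
        truth.warnings.append(
            f"planted interval holds {n_in_roh} markers, fewer than the "
            f"detector minimum of {min_segment_snps}"
        )
    return matrix, truth


def _cohort_sample_ids(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    samples = list(config.case_ids) + list(config.relative_ids)
    samples += [f"pop{i+1}" for i in range(config.n_population_controls)]
    samples += [f"panel{i+1}" for i in range(config.n_panel_controls)]
    roles = {s: "case" for s in config.case_ids}
    roles.update({s: "control" for s in config.relative_ids})
    roles.update({f"pop{i+1}": "control" for i in range(config.n_population_controls)})
    roles.update({f"panel{i+1}": "panel" for i in range(config.n_panel_controls)})
    return samples, roles


def _classify_codon_change(cds: str, p: int, alt: str) -> str:
    """Brute-force SNV class via codon translation (simulator-internal)."""
    ci = (p - 1) // 3
    codon = cds[3 * ci : 3 * ci + 3]
    within = (p - 1) % 3
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    return "synonymous" if alt_aa == ref_aa else "missense"


def _find_cds_snv(
    tx: TranscriptModel, want: str, rng: np.random.Generator, used: set[tuple[str, int]]
) -> VariantRecord:
    """Random SNV in ``tx`` with the requested coding class (plus strand genes only
    host decoys here, which keeps ref lookup trivial)."""
    cds = tx.cds_sequence
    n = len(cds) - 3  # avoid touching the stop codon
    for _ in range(10_000):
        p = int(rng.integers(4, n + 1))  # avoid the start codon too
        ref = cds[p - 1]
        alt = BASES[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        if _classify_codon_change(cds, p, alt) != want:
            continue
        gpos = cds_to_genomic(p, tx)
        if (tx.chrom, gpos) in used:
            continue
        if tx.strand == "-":
            ref, alt = str(Seq(ref).complement()), str(Seq(alt).complement())
        return VariantRecord(tx.chrom, gpos, ref, alt)
    raise RuntimeError(f"could not place a {want} decoy in {tx.id}")


def simulate_variant_cohort(
    reference: ReferenceBundle, config: SimConfig
) -> tuple[CohortGenotypes, SimTruth]:
    """Cohort + panel variant calls with one planted causal nonsense variant.

    The causal C>T sits at the configured spliced CDS position of the
    designated transcript: hom-alt in every case, het in the obligate
    carriers (parent and grandparent), het in one of three unaffected
    siblings, het in exactly ``n_population_carriers`` population dogs, and
    absent from the control panel. Decoys cover each funnel failure mode:
    case-specific but non-exonic, exonic outside the shared interval, exonic
    in-interval but violating recessive segregation (one case het), exonic
    in-interval but synonymous, and exonic in-interval but present
    homozygous in the panel. Background variants arrive at
    ``background_variant_rate`` per bp with Hardy-Weinberg genotypes, forced
    homozygous-reference across the planted interval in the haplotype
    carriers (the shared haplotype carries reference alleles).

    Returns the combined cohort (roles case/control/panel) and ground truth;
    the panel is addressable via ``cohort.sample_ids('panel')``.
    """
    rng = _rng(config, _STREAM_COHORT)
    samples, roles = _cohort_sample_ids(config)
    n_s = len(samples)
    col = {s: j for j, s in enumerate(samples)}
    case_cols = [col[s] for s in config.case_ids]
    rel_ids = list(config.relative_ids)
    obligate_cols = [
        col[s] for s, r in zip(rel_ids, config.relative_roles) if r in ("parent", "grandparent")
    ]
    sib_cols = [col[s] for s, r in zip(rel_ids, config.relative_roles) if r == "sibling"]
    pop_cols = [col[f"pop{i+1}"] for i in range(config.n_population_controls)]
    panel_cols = [col[f"panel{i+1}"] for i in range(config.n_panel_controls)]
    roh_chrom, roh_start, roh_end = config.planted_roh

    truth = SimTruth(sample_roles=dict(roles))
    used: set[tuple[str, int]] = set()
    records: list[tuple[VariantRecord, np.ndarray]] = []

    def case_specific_row() -> np.ndarray:
        row = np.zeros(n_s, dtype=np.int8)
        row[case_cols] = HOM_ALT
        return row

    tx = reference.designated if config.n_genes else None

    if tx is not None:
        _, cds_pos, c_ref, c_alt = config.causal_spec
        gpos = cds_to_genomic(cds_pos, tx)
        causal = VariantRecord(tx.chrom, gpos, c_ref, c_alt)
        row = np.zeros(n_s, dtype=np.int8)
        row[case_cols] = HOM_ALT
        row[obligate_cols] = HET
        if sib_cols:
            row[sib_cols[0]] = HET  # one of three healthy sibs is a carrier
        carrier_pop = rng.choice(pop_cols, size=config.n_population_carriers, replace=False)
        row[carrier_pop] = HET
        records.append((causal, row))
        used.add((causal.chrom, causal.pos))
        truth.causal_variant_id = causal.key

    if tx is not None and config.background_variant_rate > 0:
        # decoys, one per funnel failure mode; they are part of the background
        # machinery, so a zero background rate leaves only the causal variant
        roh_txs = [
            t for t in reference.transcripts
            if t.chrom == roh_chrom and t.cds_start >= roh_start and t.cds_end <= roh_end
        ]
        out_txs = [t for t in reference.transcripts if t not in roh_txs]
        decoy_tx = roh_txs[-1] if roh_txs else tx

        for _ in range(10_000):
            p = int(rng.integers(roh_start, roh_end + 1))
            in_exon = any(
                s <= p <= e for t in roh_txs for s, e in t.exons
            )
            if not in_exon and (roh_chrom, p) not in used:
                ref = reference.contigs[roh_chrom][p - 1]
                alt = BASES[(BASES.index(ref) + 1) % 4]
                v = VariantRecord(roh_chrom, p, ref, alt)
                records.append((v, case_specific_row()))
                used.add((roh_chrom, p))
                truth.decoy_ids["non_exonic"] = v.key
                break

        if out_txs:
            v = _find_cds_snv(out_txs[0], "missense", rng, used)
            records.append((v, case_specific_row()))
            used.add((v.chrom, v.pos))
            truth.decoy_ids["exonic_outside_roh"] = v.key

        v = _find_cds_snv(decoy_tx, "missense", rng, used)
        row = case_specific_row()
        row[case_cols[-1]] = HET  # violates recessive segregation
        records.append((v, row))
        used.add((v.chrom, v.pos))
        truth.decoy_ids["segregation_violating"] = v.key

        v = _find_cds_snv(decoy_tx, "synonymous", rng, used)
        records.append((v, case_specific_row()))
        used.add((v.chrom, v.pos))
        truth.decoy_ids["synonymous"] = v.key

        v = _find_cds_snv(decoy_tx, "missense", rng, used)
        row = case_specific_row()
        row[panel_cols[:2]] = HOM_ALT  # panel hit defeats case-specificity
        records.append((v, row))
        used.add((v.chrom, v.pos))
        truth.decoy_ids["panel_hit"] = v.key

    # Poisson background across the genome
    total_bp = config.n_contigs * config.contig_length_bp
    n_bg = int(rng.poisson(config.background_variant_rate * total_bp))
    n_redrawn = 0
    hap_cols = case_cols + obligate_cols
    placed = 0
    while placed < n_bg:
        contig = config.contig_names[int(rng.integers(0, config.n_contigs))]
        p = int(rng.integers(1, config.contig_length_bp + 1))
        if (contig, p) in used:
            n_redrawn += 1
            continue
        ref = reference.contigs[contig][p - 1]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        freq = rng.uniform(0.01, 0.5)
        row = rng.binomial(2, freq, size=n_s).astype(np.int8)
        if contig == roh_chrom and roh_start <= p <= roh_end:
            row[hap_cols] = HOM_REF  # shared haplotype carries the reference allele
        records.append((VariantRecord(contig, p, ref, alt), row))
        used.add((contig, p))
        placed += 1
    if n_redrawn:
        truth.warnings.append(f"{n_redrawn} background positions redrawn after collisions")

    order = {c: i for i, c in enumerate(config.contig_names)}
    records.sort(key=lambda r: (order[r[0].chrom], r[0].pos))
    variants = [r[0] for r in records]
    calls = (
        np.stack([r[1] for r in records], axis=0)
        if records
        else np.zeros((0, n_s), dtype=np.int8)
    )
    cohort = CohortGenotypes(variants, samples, {s: roles[s] for s in samples}, calls)
    return cohort, truth


def build_sample_sheet(config: SimConfig) -> SampleSheet:
    """Phenotype/relation sheet for the cohort samples (panel excluded)."""
    rows = [SampleInfo(s, "affected", "case") for s in config.case_ids]
    for s, role in zip(config.relative_ids, config.relative_roles):
        relation = role if role in ("parent", "grandparent", "sibling") else "other"
        rows.append(
            SampleInfo(s, "unaffected", relation, obligate_carrier=role in ("parent", "grandparent"))
        )
    rows += [
        SampleInfo(f"pop{i+1}", "unaffected", "population")
        for i in range(config.n_population_controls)
    ]
    return SampleSheet(rows)


def simulate_bundle(config: SimConfig | None = None) -> SimBundle:
    """Build the complete synthetic study from one configuration."""
    config = config or SimConfig()
    reference = build_reference(config)
    array, array_truth = simulate_array_genotypes(reference, config)
    cohort, truth = simulate_variant_cohort(reference, config)
    truth.planted_roh_intervals_per_case = array_truth.planted_roh_intervals_per_case
    truth.warnings = array_truth.warnings + truth.warnings
    # array truth knows array-plate roles; cohort truth the cohort roles
    merged_roles = dict(array_truth.sample_roles)
    merged_roles.update(truth.sample_roles)
    truth.sample_roles = merged_roles
    return SimBundle(config, reference, array, cohort, build_sample_sheet(config), truth)
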