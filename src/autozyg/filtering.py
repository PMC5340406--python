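"""Case-specific recessive variant filtering funnel against a control panel.

The funnel reproduces the canonical WGS prioritisation for a recessive
Mendelian trait mapped by autozygosity: (1) keep variants homozygous-alt in
every affected individual and effectively absent from a panel of unrelated
control genomes, (2) restrict to exonic variants, (3) restrict to the shared
homozygous regions from ROH mapping, (4) restrict to protein-changing
classes (missense, nonsense, frameshift). Each stage records a label and a
non-increasing survivor count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .consequence import (
    Consequence,
    EFFECT_SEVERITY,
    TranscriptModel,
    VariantRecord,
    annotate_best,
)
from .roh import HET, HOM_ALT, HOM_REF, MISSING, SharedRegion

__all__ = [
    "CohortGenotypes",
    "FilterPolicy",
    "FilterFunnel",
    "PROTEIN_CHANGING_CLASSES",
    "STAGE_LABELS",
    "recessive_case_specific",
    "restrict_exonic",
    "restrict_to_regions",
    "effect_class_filter",
    "run_funnel",
]

PROTEIN_CHANGING_CLASSES = frozenset({"missense", "nonsense", "frameshift"})

STAGE_LABELS = (
    "Total number of variants",
    "Variants that segregate under recessive mode of inheritance",
    "Variants in the exonic regions",
    "Variants in the identified regions of homozygosity",
    "Non-synonymous, frameshift and nonsense variants in the regions of homozygosity",
)

ROLES = ("case", "control", "panel")


@dataclass
class CohortGenotypes:
    """Variant x sample genotype calls with per-sample role labels.

    Roles: ``case`` (affected), ``control`` (unaffected cohort members used
    for segregation / association, including relatives and population dogs),
    ``panel`` (unrelated control genomes used for case-specificity).
    """

    variants: list[VariantRecord]
    samples: list[str]
    roles: dict[str, str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError("calls shape inconsistent with variants x samples")
        for s in self.samples:
            if self.roles.get(s) not in ROLES:
                raise ValueError(f"sample {s!r} has invalid role {self.roles.get(s)!r}")

    def sample_ids(self, role: str) -> list[str]:
        return [s for s in self.samples if self.roles[s] == role]

    def columns(self, role: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.roles[s] == role], dtype=int)

    def variant_index(self) -> dict[str, int]:
        return {v.key: i for i, v in enumerate(self.variants)}

    def genotypes_for(self, variant_id: str) -> dict[str, int]:
        """Per-sample genotype codes for one variant."""
        i = self.variant_index()[variant_id]
        return {s: int(self.calls[i, j]) for j, s in enumerate(self.samples)}


@dataclass(frozen=True)
class FilterPolicy:
    """Tolerances of the case-specificity stage.

    ``treat_missing_as='exclude'`` drops a variant when any case call is
    missing (missing panel calls are ignored); ``'ref'`` treats every missing
    call as homozygous reference. ``case_missing_as_hom_alt`` relaxes the
    case requirement for degraded (e.g. FFPE) samples.
    """

    require_case_hom_alt: bool = True
    max_panel_hom_alt: int = 0
    max_panel_het: int = 0
    treat_missing_as: str = "exclude"
    case_missing_as_hom_alt: bool = False

    def __post_init__(self) -> None:
        if self.max_panel_hom_alt < 0 or self.max_panel_het < 0:
            raise ValueError("panel tolerances must be >= 0")
        if self.treat_missing_as not in ("exclude", "ref"):
            raise ValueError("treat_missing_as must be 'exclude' or 'ref'")


@dataclass
class FilterFunnel:
    """Ordered (label, count) stages plus surviving variant ids per stage."""

    stages: list[tuple[str, int]] = field(default_factory=list)
    surviving_ids: list[set[str]] = field(default_factory=list)

    def add(self, label: str, ids: set[str]) -> None:
        if self.stages and len(ids) > self.stages[-1][1]:
            raise ValueError("funnel counts must be non-increasing")
        self.stages.append((label, len(ids)))
        self.surviving_ids.append(set(ids))

    @property
    def final_ids(self) -> set[str]:
        return set(self.surviving_ids[-1]) if self.surviving_ids else set()

    def to_rows(self) -> list[dict]:
        return [{"step": lab, "n_variants": n} for lab, n in self.stages]


def recessive_case_specific(
    cohort: CohortGenotypes, policy: FilterPolicy = FilterPolicy()
) -> set[str]:
    """Variants hom-alt in every case and (near-)absent from the panel."""
    case_cols = cohort.columns("case")
    if case_cols.size == 0:
        raise ValueError("cohort has no case samples")
    panel_cols = cohort.columns("panel")
    calls = cohort.calls

    cg = calls[:, case_cols]
    if policy.treat_missing_as == "ref":
        cg = np.where(cg == MISSING, HOM_REF, cg)
    if policy.case_missing_as_hom_alt:
        cg = np.where(cg == MISSING, HOM_ALT, cg)
    if policy.require_case_hom_alt:
        keep = (cg == HOM_ALT).all(axis=1)
    else:
        keep = (cg != HOM_REF).all(axis=1) & (cg != MISSING).all(axis=1)

    if panel_cols.size:
        pg = calls[:, panel_cols]
        if policy.treat_missing_as == "ref":
            pg = np.where(pg == MISSING, HOM_REF, pg)
        keep &= (pg == HOM_ALT).sum(axis=1) <= policy.max_panel_hom_alt
        keep &= (pg == HET).sum(axis=1) <= policy.max_panel_het
    return {cohort.variants[i].key for i in np.flatnonzero(keep)}


def _exon_trees(transcripts: list[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        tree = trees.setdefault(tx.chrom, IntervalTree())
        for start, end in tx.exons:
            tree.addi(start, end + 1)  # tree is half-open
    return trees


def restrict_exonic(
    ids: set[str], variants: list[VariantRecord], transcripts: list[TranscriptModel]
) -> set[str]:
    """Keep variants overlapping any annotated exon (1-based inclusive)."""
    trees = _exon_trees(transcripts)
    out: set[str] = set()
    for v in variants:
        if v.key not in ids:
            continue
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlap(v.pos, v.end + 1):
            out.add(v.key)
    return out


def restrict_to_regions(
    ids: set[str], variants: list[VariantRecord], regions: list[SharedRegion]
) -> set[str]:
    """Keep variants whose position lies inside a shared homozygous region."""
    by_chrom: dict[str, list[SharedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: set[str] = set()
    for v in variants:
        if v.key not in ids:
            continue
        for r in by_chrom.get(v.chrom, ()):
            if r.start_bp <= v.pos <= r.end_bp:
                out.add(v.key)
                break
    return out


def effect_class_filter(
    ids: set[str],
    consequences: dict[str, Consequence],
    keep: frozenset[str] | set[str] = PROTEIN_CHANGING_CLASSES,
) -> set[str]:
    """Keep variants whose (best) consequence class is in ``keep``."""
    missing = ids - consequences.keys()
    if missing:
        raise ValueError(f"no consequence available for {sorted(missing)[:5]} ...")
    return {i for i in ids if consequences[i].effect_class in keep}


def run_funnel(
    cohort: CohortGenotypes,
    transcripts: list[TranscriptModel],
    regions: list[SharedRegion],
    policy: FilterPolicy = FilterPolicy(),
) -> FilterFunnel:
    """Apply the four filtering stages in order and record the count ledger.

    Consequences are computed only for variants surviving the region stage
    (the earlier stages do not need them); each surviving variant gets its
    most severe consequence across all overlapping transcripts.
    """
    funnel = FilterFunnel()
    all_ids = {v.key for v in cohort.variants}
    funnel.add(STAGE_LABELS[0], all_ids)

    s1 = recessive_case_specific(cohort, policy)
    funnel.add(STAGE_LABELS[1], s1)

    s2 = restrict_exonic(s1, cohort.variants, transcripts)
    funnel.add(STAGE_LABELS[2], s2)

    s3 = restrict_to_regions(s2, cohort.variants, regions)
    funnel.add(STAGE_LABELS[3], s3)

    cons = {
        v.key: annotate_best(v, transcripts) for v in cohort.variants if v.key in s3
    }
    s4 = effect_class_filter(s3, cons)
    funnel.add(STAGE_LABELS[4], s4)
    return funnel
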