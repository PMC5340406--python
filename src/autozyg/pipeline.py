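"""End-to-end discovery pipeline: QC -> ROH -> shared regions -> funnel ->
segregation -> carrier screen -> allelic association."""

from __future__ import annotations

from dataclasses import dataclass, field

from .consequence import Consequence, TranscriptModel, annotate_best
from .filtering import CohortGenotypes, FilterFunnel, FilterPolicy, run_funnel
from .roh import (
    GenotypeMatrix,
    QCLog,
    QCThresholds,
    ROHParams,
    ROHSegment,
    SharedRegion,
    detect_roh,
    qc_filter,
    shared_regions,
)
from .segregation import (
    AssocResult,
    CarrierEstimate,
    SegregationReport,
    allelic_chisq,
    build_allelic_table,
    carrier_frequency,
    check_recessive_segregation,
)
from .simulate import SimBundle

__all__ = ["DiscoveryResult", "run_discovery"]


@dataclass
class DiscoveryResult:
    """Everything the pipeline computes on one study."""

    qc_log: QCLog
    roh_by_case: dict[str, list[ROHSegment]]
    regions: list[SharedRegion]
    funnel: FilterFunnel
    candidate_consequences: dict[str, Consequence]
    segregation: dict[str, SegregationReport]
    fully_segregating_ids: list[str] = field(default_factory=list)
    carrier: CarrierEstimate | None = None
    association: AssocResult | None = None

    @property
    def top_candidate(self) -> str | None:
        return self.fully_segregating_ids[0] if self.fully_segregating_ids else None


def run_discovery(
    bundle: SimBundle,
    qc: QCThresholds = QCThresholds(),
    roh_params: ROHParams = ROHParams(),
    policy: FilterPolicy = FilterPolicy(),
    include_relatives_in_association: bool = True,
) -> DiscoveryResult:
    """Run the whole mapping analysis on one (simulated or loaded) study.

    Case ROH are intersected into shared regions, the variant funnel is run
    against those regions, surviving candidates are segregation-checked
    against the pedigree, and for each fully segregating candidate the
    population carrier frequency and the allelic chi-square (cases vs all
    unaffected cohort members, relatives pooled by default) are computed.
    """
    log = QCLog()
    clean = qc_filter(bundle.array, qc, log)
    case_ids = [s for s in bundle.config.case_ids if s in clean.samples]
    roh_by_case = {c: detect_roh(clean, c, roh_params) for c in case_ids}
    regions = shared_regions(roh_by_case, clean)
    funnel = run_funnel(bundle.cohort, bundle.reference.transcripts, regions, policy)

    cons = {
        vid: annotate_best(v, bundle.reference.transcripts)
        for v in bundle.cohort.variants
        for vid in (v.key,)
        if vid in funnel.final_ids
    }
    segregation: dict[str, SegregationReport] = {}
    fully = []
    for vid in sorted(funnel.final_ids):
        genos = bundle.cohort.genotypes_for(vid)
        report = check_recessive_segregation(genos, bundle.sheet)
        segregation[vid] = report
        if report.fully_segregating:
            fully.append(vid)

    carrier = None
    assoc = None
    if fully:
        vid = fully[0]
        genos = bundle.cohort.genotypes_for(vid)
        pop_ids = [r.sample for r in bundle.sheet if r.relation == "population"]
        carrier = carrier_frequency(genos, pop_ids)
        control_ids = (
            [r.sample for r in bundle.sheet if r.relation != "case"]
            if include_relatives_in_association
            else pop_ids
        )
        table = build_allelic_table(
            [genos[s] for s in bundle.sheet.case_ids if s in genos],
            [genos[s] for s in control_ids if s in genos],
        )
        assoc = allelic_chisq(table)

    return DiscoveryResult(
        qc_log=log,
        roh_by_case=roh_by_case,
        regions=regions,
        funnel=funnel,
        candidate_consequences=cons,
        segregation=segregation,
        fully_segregating_ids=fully,
        carrier=carrier,
        association=assoc,
    )
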