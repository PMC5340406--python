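"""Runs-of-homozygosity detection and case intersection from array genotypes.

Implements the classic sliding-window ROH search used for autozygosity
mapping of recessive traits: genotypes are QC-filtered (marker call rate,
sample call rate, minor allele frequency), per-sample homozygous segments
are called by scanning fixed-size SNP windows that tolerate a bounded number
of heterozygous and missing calls, and the affected individuals' segments
are intersected into shared regions that additionally require identical
homozygous alleles across all cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "QCThresholds",
    "GenotypeMatrix",
    "ROHParams",
    "ROHSegment",
    "SharedRegion",
    "QCLog",
    "EmptyMatrixError",
    "qc_filter",
    "detect_roh",
    "shared_regions",
]

# genotype codes shared across the package
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


class EmptyMatrixError(ValueError):
    """QC removed every marker (or every sample)."""


@dataclass(frozen=True)
class QCThresholds:
    """Array QC regime: strict lower bounds (values must exceed them)."""

    min_snp_call_rate: float = 0.95
    min_sample_call_rate: float = 0.95
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_sample_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Biallelic array genotypes over ordered markers x samples.

    ``calls`` is an int8 array of shape (n_markers, n_samples) with codes
    HOM_REF/HET/HOM_ALT/MISSING; allele A is the "ref" allele of the code.
    Markers must be strictly sorted by (chrom, pos) with chromosomes grouped.
    """

    chroms: np.ndarray
    positions: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    marker_ids: np.ndarray
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.calls.shape != (n, len(self.samples)):
            raise ValueError("calls shape inconsistent with markers x samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != n:
            raise ValueError("duplicate marker ids")
        seen: dict[str, int] = {}
        last_chrom = None
        for i, c in enumerate(self.chroms):
            if c != last_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c} not contiguous")
                seen[c] = i
                last_chrom = c
            elif i and self.positions[i] <= self.positions[i - 1]:
                raise ValueError(f"positions not strictly increasing on {c}")
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("invalid genotype codes present")

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chrom, slice) blocks in marker order."""
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or self.chroms[i] != self.chroms[start]:
                out.append((str(self.chroms[start]), slice(start, i)))
                start = i
        return out

    def subset(self, marker_mask: np.ndarray, sample_mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chroms[marker_mask],
            self.positions[marker_mask],
            self.allele_a[marker_mask],
            self.allele_b[marker_mask],
            self.marker_ids[marker_mask],
            [s for s, k in zip(self.samples, sample_mask) if k],
            self.calls[np.ix_(marker_mask, sample_mask)],
        )


@dataclass
class QCLog:
    """Removal bookkeeping from :func:`qc_filter`, in application order."""

    n_samples_removed_call_rate: int = 0
    n_markers_removed_call_rate: int = 0
    n_markers_removed_maf: int = 0
    removed_samples: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH parameters (defaults follow the common v1.07 tool defaults)."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    window_hit_threshold: float = 0.05
    min_segment_snps: int = 100
    min_segment_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_segment_snps < 1:
            raise ValueError("window and segment SNP counts must be positive")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if min(self.min_segment_kb, self.min_density_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("kb parameters must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One per-sample homozygous run; coordinates are outermost eligible markers."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass(frozen=True)
class SharedRegion:
    """Interval homozygous (for the same allele) in every case."""

    chrom: str
    start_bp: int
    end_bp: int
    n_cases_supporting: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def qc_filter(
    matrix: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    log: QCLog | None = None,
) -> GenotypeMatrix:
    """Apply array QC: sample call rate first, then marker call rate and MAF.

    MAF is computed on post-sample-filter calls, so marker retention reflects
    the cleaned cohort. Marker order is preserved. Raises
    :class:`EmptyMatrixError` if nothing survives. Idempotent.
    """
    if matrix.n_markers == 0 or not matrix.samples:
        raise EmptyMatrixError("input matrix is empty")
    calls = matrix.calls
    nonmissing = calls != MISSING

    sample_rate = nonmissing.mean(axis=0)
    keep_s = sample_rate > thresholds.min_sample_call_rate
    if log is not None:
        log.n_samples_removed_call_rate = int((~keep_s).sum())
        log.removed_samples = [s for s, k in zip(matrix.samples, keep_s) if not k]
    if not keep_s.any():
        raise EmptyMatrixError("every sample failed the call-rate filter")

    calls_s = calls[:, keep_s]
    nm = calls_s != MISSING
    n_called = nm.sum(axis=1)
    marker_rate = n_called / calls_s.shape[1]
    keep_rate = marker_rate > thresholds.min_snp_call_rate

    n_alt = np.where(nm, calls_s, 0).sum(axis=1)  # codes 0/1/2 count B alleles
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_called > 0, n_alt / (2 * n_called), 0.0)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    keep_maf = maf > thresholds.min_maf

    keep_m = keep_rate & keep_maf
    if log is not None:
        log.n_markers_removed_call_rate = int((~keep_rate).sum())
        log.n_markers_removed_maf = int((keep_rate & ~keep_maf).sum())
    if not keep_m.any():
        raise EmptyMatrixError("every marker failed QC")
    return matrix.subset(keep_m, keep_s)


def _window_hom(gt: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per window-start: window passes the het/missing tolerance."""
    w = params.window_snps
    n = gt.size
    if n < w:
        return np.zeros(0, dtype=bool)
    het = (gt == HET).astype(np.int32)
    mis = (gt == MISSING).astype(np.int32)
    kern = np.ones(w, dtype=np.int32)
    het_w = np.convolve(het, kern, mode="valid")
    mis_w = np.convolve(mis, kern, mode="valid")
    return (het_w <= params.max_het_per_window) & (mis_w <= params.max_missing_per_window)


def _eligible_markers(gt: np.ndarray, params: ROHParams) -> np.ndarray:
    """Marker eligibility: fraction of covering windows that are homozygous."""
    w = params.window_snps
    n = gt.size
    hom = _window_hom(gt, params)
    if hom.size == 0:
        return np.zeros(n, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(hom.astype(np.int64))))
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    n_cover = hi - lo + 1
    n_hom = csum[hi + 1] - csum[lo]
    return n_hom / n_cover >= params.window_hit_threshold


def detect_roh(
    matrix: GenotypeMatrix, sample: str, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Detect runs of homozygosity for one sample by sliding SNP windows.

    Per chromosome, every contiguous window of ``window_snps`` markers is
    scored homozygous if it holds at most ``max_het_per_window`` het and
    ``max_missing_per_window`` missing calls; a marker is eligible when the
    homozygous fraction of windows covering it reaches
    ``window_hit_threshold``. Maximal runs of eligible markers are split at
    inter-marker gaps above ``max_gap_kb`` and reported when they satisfy the
    SNP-count, physical-length and SNP-density minima. Segment bounds are the
    outermost eligible marker positions; segments never span chromosomes.
    """
    j = matrix.sample_index(sample)
    segments: list[ROHSegment] = []
    for chrom, sl in matrix.chrom_slices():
        gt = matrix.calls[sl, j]
        pos = matrix.positions[sl]
        elig = _eligible_markers(gt, params)
        idx = np.flatnonzero(elig)
        if idx.size == 0:
            continue
        # split runs at index discontinuities and at large physical gaps
        brk = np.flatnonzero(
            (np.diff(idx) > 1)
            | (np.diff(pos[idx]) > params.max_gap_kb * 1000.0)
        )
        for run in np.split(idx, brk + 1):
            seg = _make_segment(str(chrom), sample, run, gt, pos, params)
            if seg is not None:
                segments.append(seg)
    return segments


def _make_segment(
    chrom: str,
    sample: str,
    run: np.ndarray,
    gt: np.ndarray,
    pos: np.ndarray,
    params: ROHParams,
) -> ROHSegment | None:
    n_snps = run.size
    if n_snps < params.min_segment_snps:
        return None
    start_bp, end_bp = int(pos[run[0]]), int(pos[run[-1]])
    length_kb = (end_bp - start_bp + 1) / 1000.0
    if length_kb < params.min_segment_kb:
        return None
    if length_kb / n_snps > params.min_density_kb_per_snp:
        return None
    inside = gt[run[0] : run[-1] + 1]
    return ROHSegment(
        sample,
        chrom,
        start_bp,
        end_bp,
        n_snps,
        int((inside == HET).sum()),
        int((inside == MISSING).sum()),
    )


def _interval_intersection(per_case: list[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Intersect unions of closed intervals across cases."""
    out = per_case[0]
    for ivs in per_case[1:]:
        nxt: list[tuple[int, int]] = []
        for a0, a1 in out:
            for b0, b1 in ivs:
                lo, hi = max(a0, b0), min(a1, b1)
                if lo <= hi:
                    nxt.append((lo, hi))
        out = sorted(nxt)
        if not out:
            break
    return out


def shared_regions(
    segments_by_case: dict[str, list[ROHSegment]],
    matrix: GenotypeMatrix,
    max_allele_mismatches: int = 0,
) -> list[SharedRegion]:
    """Intersect case ROH into shared autozygous regions with allele sharing.

    A shared region is a maximal interval covered by at least one ROH segment
    of *every* case, in which all cases are homozygous for the same allele at
    every non-missing marker. Markers where any case is missing are ignored;
    a marker where any case is het, or where cases are homozygous for
    opposite alleles, counts as a mismatch. Regions are split at mismatching
    markers once more than ``max_allele_mismatches`` accumulate (default 0:
    split at every mismatch), with boundaries trimmed to conforming markers.
    Output is sorted and non-overlapping.
    """
    if not segments_by_case:
        return []
    cases = sorted(segments_by_case)
    n_cases = len(cases)
    chroms = sorted({s.chrom for segs in segments_by_case.values() for s in segs})
    case_cols = [matrix.sample_index(c) for c in cases]
    chrom_blocks = dict((c, sl) for c, sl in matrix.chrom_slices())

    regions: list[SharedRegion] = []
    for chrom in chroms:
        per_case = []
        for c in cases:
            ivs = sorted(
                (s.start_bp, s.end_bp) for s in segments_by_case[c] if s.chrom == chrom
            )
            per_case.append(ivs)
        if any(not ivs for ivs in per_case):
            continue
        for lo, hi in _interval_intersection(per_case):
            regions.extend(
                _split_by_allele_sharing(
                    chrom, lo, hi, matrix, chrom_blocks.get(chrom), case_cols,
                    n_cases, max_allele_mismatches,
                )
            )
    return sorted(regions, key=lambda r: (r.chrom, r.start_bp))


def _split_by_allele_sharing(
    chrom: str,
    lo: int,
    hi: int,
    matrix: GenotypeMatrix,
    block: slice | None,
    case_cols: list[int],
    n_cases: int,
    allowance: int,
) -> list[SharedRegion]:
    if n_cases == 1 or block is None:
        return [SharedRegion(chrom, lo, hi, n_cases)]
    pos = matrix.positions[block]
    sub = matrix.calls[block][:, case_cols]
    inside = (pos >= lo) & (pos <= hi)
    if not inside.any():
        return [SharedRegion(chrom, lo, hi, n_cases)]
    g = sub[inside]
    p = pos[inside]
    informative = (g != MISSING).all(axis=1)
    hom_shared = informative & (g != HET).all(axis=1) & (g == g[:, :1]).all(axis=1)
    mismatch = informative & ~hom_shared

    out: list[SharedRegion] = []
    start = lo
    budget = allowance
    last_ok: int | None = None
    for i in range(g.shape[0]):
        if not informative[i]:
            continue
        if mismatch[i]:
            if budget > 0:
                budget -= 1
                continue
            if last_ok is not None:
                out.append(SharedRegion(chrom, start, int(last_ok), n_cases))
            start_next = int(p[i + 1 :][informative[i + 1 :]][0]) if informative[i + 1 :].any() else None
            if start_next is None:
                return out
            start = start_next
            budget = allowance
            last_ok = None
        else:
            last_ok = int(p[i])
    end = hi if last_ok is not None else None
    if end is not None:
        out.append(SharedRegion(chrom, start, hi, n_cases))
    return out
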