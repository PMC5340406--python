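"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, a hard-coded codon
table, quadrature) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

# standard nuclear codon table, written out so translation is independent of
# any library the implementation might use
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def translate_oracle(cds: str) -> str:
    """Translate codon by codon, stopping at the first stop codon."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def classify_snv_oracle(cds: str, cds_pos: int, alt: str) -> str:
    """Classify a CDS SNV by translating the whole ref and alt CDS."""
    prot_ref = translate_oracle(cds)
    mutated = cds[: cds_pos - 1] + alt + cds[cds_pos:]
    prot_alt = translate_oracle(mutated)
    if prot_alt == prot_ref:
        return "synonymous"
    if len(prot_alt) < len(prot_ref) and prot_ref.startswith(prot_alt):
        return "nonsense"
    return "missense"


def cds_genomic_coords(exons, strand: str) -> list[int]:
    """Genomic coordinate of every spliced CDS base, in transcript order."""
    positions: list[int] = []
    for s, e in exons:
        positions.extend(range(s, e + 1))
    return positions[::-1] if strand == "-" else positions


def roh_oracle(gt, pos, params):
    """Exhaustive sliding-window ROH evaluation on one chromosome.

    Returns (start_bp, end_bp, n_snps) triples. gt uses the package codes
    (0 hom-ref / 1 het / 2 hom-alt / -1 missing).
    """
    n = len(gt)
    w = params.window_snps
    hom_windows = []
    for i in range(n - w + 1):
        win = list(gt[i : i + w])
        ok = (
            sum(1 for g in win if g == 1) <= params.max_het_per_window
            and sum(1 for g in win if g == -1) <= params.max_missing_per_window
        )
        hom_windows.append(ok)
    eligible = []
    for j in range(n):
        covering = [
            hom_windows[i] for i in range(max(0, j - w + 1), min(j, n - w) + 1)
        ]
        eligible.append(
            bool(covering) and sum(covering) / len(covering) >= params.window_hit_threshold
        )

    segments = []

    def flush(run):
        if not run:
            return
        start, end = pos[run[0]], pos[run[-1]]
        kb = (end - start + 1) / 1000.0
        if (
            len(run) >= params.min_segment_snps
            and kb >= params.min_segment_kb
            and kb / len(run) <= params.min_density_kb_per_snp
        ):
            segments.append((int(start), int(end), len(run)))

    run: list[int] = []
    for j in range(n):
        if eligible[j]:
            if run and pos[j] - pos[run[-1]] > params.max_gap_kb * 1000:
                flush(run)
                run = []
            run.append(j)
        else:
            flush(run)
            run = []
    flush(run)
    return segments


def chi2_sf_quad(x: float) -> float:
    """chi-square(1) upper tail by quadrature of the density."""
    pdf = lambda t: math.exp(-t / 2.0) / math.sqrt(2.0 * math.pi * t)
    val, _ = quad(pdf, x, np.inf, epsabs=0, epsrel=1e-13)
    return val


def jaccard(intervals_a, intervals_b) -> float:
    """Jaccard overlap of two closed-interval sets on one chromosome."""
    def length(ivs):
        return sum(e - s + 1 for s, e in ivs)

    inter = 0
    for a0, a1 in intervals_a:
        for b0, b1 in intervals_b:
            lo, hi = max(a0, b0), min(a1, b1)
            if lo <= hi:
                inter += hi - lo + 1
    union = length(intervals_a) + length(intervals_b) - inter
    return inter / union if union else 1.0
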