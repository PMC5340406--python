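"""Pedigree segregation checking, carrier screening and allelic association.

Validates a candidate recessive variant the way a mapping study does after
the filtering funnel: every affected individual must be homozygous for the
alternate allele, every obligate carrier (parent / grandparent of an
affected) heterozygous, and unaffected non-obligate relatives either
heterozygous or homozygous reference. A population screen estimates carrier
frequency, and a 2x2 allelic chi-square tests case/control allele counts,
with extreme-tail p-values computed through the complementary error
function so that values far below the double underflow of 1 - CDF remain
exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.special import erfc

from .roh import HET, HOM_ALT, HOM_REF, MISSING

__all__ = [
    "SampleInfo",
    "SampleSheet",
    "SegregationReport",
    "AllelicTable",
    "AssocResult",
    "CarrierEstimate",
    "check_recessive_segregation",
    "carrier_frequency",
    "build_allelic_table",
    "allelic_chisq",
    "allelic_fisher",
    "chi2_sf_df1",
]

PHENOTYPES = ("affected", "unaffected")
RELATIONS = ("case", "parent", "grandparent", "sibling", "population", "other")

_GENO_NAMES = {HOM_REF: "hom-ref", HET: "het", HOM_ALT: "hom-alt", MISSING: "missing"}


@dataclass(frozen=True)
class SampleInfo:
    sample: str
    phenotype: str
    relation: str
    obligate_carrier: bool = False

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"invalid phenotype {self.phenotype!r}")
        if self.relation not in RELATIONS:
            raise ValueError(f"invalid relation {self.relation!r}")
        if (self.phenotype == "affected") != (self.relation == "case"):
            raise ValueError("affected phenotype must coincide with relation 'case'")


@dataclass
class SampleSheet:
    rows: list[SampleInfo]

    def __post_init__(self) -> None:
        ids = [r.sample for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sheet")

    def __iter__(self):
        return iter(self.rows)

    @property
    def case_ids(self) -> list[str]:
        return [r.sample for r in self.rows if r.relation == "case"]


@dataclass
class SegregationReport:
    """Outcome of a recessive-model consistency check over a pedigree."""

    n_consistent: int
    inconsistencies: list[tuple[str, tuple[str, ...], str]] = field(default_factory=list)

    @property
    def fully_segregating(self) -> bool:
        return not self.inconsistencies


@dataclass(frozen=True)
class AllelicTable:
    """2x2 allele counts: rows cases/controls, columns alt/ref alleles."""

    case_alt: int
    case_ref: int
    control_alt: int
    control_ref: int

    def __post_init__(self) -> None:
        if min(self.case_alt, self.case_ref, self.control_alt, self.control_ref) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.case_alt + self.case_ref + self.control_alt + self.control_ref

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.case_alt, self.case_ref], [self.control_alt, self.control_ref]],
            dtype=float,
        )


@dataclass(frozen=True)
class AssocResult:
    chi_square: float
    df: int
    p_value: float
    log10_p: float

    def __post_init__(self) -> None:
        if self.chi_square < 0:
            raise ValueError("chi_square must be >= 0")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")


@dataclass(frozen=True)
class CarrierEstimate:
    n_het: int
    n_screened: int
    frequency_pct: float
    n_genetically_affected: int = 0

    def __post_init__(self) -> None:
        if self.n_het > self.n_screened:
            raise ValueError("n_het cannot exceed n_screened")


def _expected_set(info: SampleInfo) -> tuple[int, ...]:
    if info.relation == "case":
        return (HOM_ALT,)
    if info.obligate_carrier:
        return (HET,)
    return (HET, HOM_REF)


def check_recessive_segregation(
    genotypes: dict[str, int], sheet: SampleSheet
) -> SegregationReport:
    """Check each pedigree sample's genotype against the recessive expectation.

    Expected genotype sets: affected -> hom-alt; obligate carrier -> het;
    other unaffecteds -> het or hom-ref. A sample present in the sheet but
    absent (or missing) in ``genotypes`` is listed as an inconsistency with
    observed 'missing' rather than silently dropped.
    """
    n_ok = 0
    bad: list[tuple[str, tuple[str, ...], str]] = []
    for info in sheet:
        expected = _expected_set(info)
        expected_names = tuple(_GENO_NAMES[g] for g in expected)
        obs = genotypes.get(info.sample, MISSING)
        if obs == MISSING:
            bad.append((info.sample, expected_names, "missing"))
        elif obs in expected:
            n_ok += 1
        else:
            bad.append((info.sample, expected_names, _GENO_NAMES[obs]))
    return SegregationReport(n_consistent=n_ok, inconsistencies=bad)


def carrier_frequency(
    genotypes: dict[str, int], population_ids: list[str]
) -> CarrierEstimate:
    """Heterozygote frequency in a population screen, 1-decimal percent.

    Homozygous-alt individuals are not carriers; they are reported separately
    as genetically affected. Rounding is half-up so e.g. 3/176 prints 1.7.
    """
    if not population_ids:
        raise ValueError("population sample list is empty")
    codes = [genotypes.get(s, MISSING) for s in population_ids]
    n_het = sum(c == HET for c in codes)
    n_hom = sum(c == HOM_ALT for c in codes)
    n = len(population_ids)
    pct = float(
        Decimal(100 * n_het) / Decimal(n)
    )
    pct = float(Decimal(str(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return CarrierEstimate(n_het, n, pct, n_hom)


def build_allelic_table(
    case_genotypes: list[int], control_genotypes: list[int]
) -> AllelicTable:
    """Count alt/ref alleles per group; missing genotypes are excluded."""

    def count(codes: list[int]) -> tuple[int, int]:
        alt = ref = 0
        for c in codes:
            if c == MISSING:
                continue
            if c == HOM_ALT:
                alt += 2
            elif c == HET:
                alt += 1
                ref += 1
            elif c == HOM_REF:
                ref += 2
            else:
                raise ValueError(f"invalid genotype code {c}")
        return alt, ref

    ca, cr = count(case_genotypes)
    ka, kr = count(control_genotypes)
    return AllelicTable(ca, cr, ka, kr)


def chi2_sf_df1(x: float) -> tuple[float, float]:
    """Survival function of chi-square(1) and its log10, via erfc.

    For df = 1, P(X > x) = erfc(sqrt(x/2)); erfc stays exact to ~1e-308 and
    beyond that an asymptotic expansion supplies log10(p).
    """
    if x < 0:
        raise ValueError("chi-square statistic must be >= 0")
    z = math.sqrt(x / 2.0)
    p = float(erfc(z))
    if p > 0.0:
        return p, math.log10(p) if p < 1 else 0.0
    # erfc underflowed: log erfc(z) ~ -z^2 - log(z sqrt(pi))
    log10p = (-z * z - math.log(z * math.sqrt(math.pi))) / math.log(10)
    return 5e-324, log10p


def allelic_chisq(table: AllelicTable) -> AssocResult:
    """Pearson chi-square on the 2x2 allele table (df=1, no continuity correction)."""
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p, log10p = chi2_sf_df1(chi2)
    return AssocResult(chi_square=chi2, df=1, p_value=min(p, 1.0), log10_p=log10p)


def allelic_fisher(table: AllelicTable) -> float:
    """Two-sided Fisher exact p-value on the allele table (alternative test)."""
    return float(stats.fisher_exact(table.as_array().astype(int))[1])
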