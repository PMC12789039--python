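"""Multi-level population attributable fractions, CIs, and allele partitioning.

The attributable fraction for a multi-level exposure is computed from case
fractions and per-level risk ratios:

    PAF_i = p_ci · (RR_i − 1) / RR_i          (per exposure level)
    PAF   = Σ_i PAF_i                          (over the risk levels)

where p_ci is the fraction of all cases falling in level i and RR_i the
risk ratio of level i against the lowest-risk reference.  This form is
algebraically identical to the excess-case fraction
(observed − counterfactual cases at reference risk) / observed cases, and
reduces to Levin's prevalence-based formula q_e(RR−1)/(1+q_e(RR−1)) for a
single exposed level.

Confidence intervals are plug-in: each PAF_i is re-evaluated at the lower
(resp. upper) RR confidence bounds and summed.  This propagates only RR
uncertainty and ignores sampling error in the case fractions, which makes
the intervals anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genotypes import GenotypeCountTable, REFERENCE_GENOTYPE
from .risk import (
    ConversionConfig,
    EstimateSet,
    RiskEstimateSet,
    convert_or_set,
    crude_or,
)

__all__ = [
    "CaseFractions",
    "PafEntry",
    "PafTable",
    "AllelePartition",
    "genotype_paf",
    "total_paf",
    "paf_from_points",
    "partition_alleles",
    "sensitivity_p0",
    "PARTITION_RULES",
]


@dataclass(frozen=True)
class CaseFractions:
    """Fractions of all cases per exposure level (p_ci); sums to one."""

    fractions: Mapping[str, float]
    case_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("case fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"case fractions must sum to 1, got {total}")

    @classmethod
    def from_counts(cls, table: GenotypeCountTable) -> "CaseFractions":
        return cls(fractions=table.case_fractions(), case_counts=dict(table.cases))

    def __getitem__(self, level: str) -> float:
        return self.fractions[level]


def genotype_paf(p_ci: float, rr: float) -> float:
    """Attributable fraction contributed by one exposure level.

    PAF_i = p_ci·(RR_i − 1)/RR_i: the share of all cases that fall in
    level i and are in excess of what the reference risk would produce.
    """
    if not (0 <= p_ci <= 1):
        raise ValueError(f"case fraction must lie in [0, 1], got {p_ci}")
    if not (rr > 0):
        raise ValueError(f"risk ratio must be positive, got {rr}")
    return p_ci * (rr - 1.0) / rr


@dataclass(frozen=True)
class PafEntry:
    paf: float
    lower: float | None = None
    upper: float | None = None


@dataclass(frozen=True)
class PafTable:
    """Per-level PAFs (fractions, not percent) with plug-in CIs and their total."""

    entries: Mapping[str, PafEntry]
    total: PafEntry
    reference: str = REFERENCE_GENOTYPE
    p0: float | None = None  # baseline risk used if an OR→RR conversion fed this table

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def __getitem__(self, level: str) -> PafEntry:
        return self.entries[level]

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        rows = [
            {
                "level": g,
                "paf": e.paf * scale,
                "lower": None if e.lower is None else e.lower * scale,
                "upper": None if e.upper is None else e.upper * scale,
            }
            for g, e in self.entries.items()
        ]
        rows.append(
            {
                "level": "total",
                "paf": self.total.paf * scale,
                "lower": None if self.total.lower is None else self.total.lower * scale,
                "upper": None if self.total.upper is None else self.total.upper * scale,
            }
        )
        return pd.DataFrame(rows)

    def to_tsv(self, path, percent: bool = True) -> None:
        self.to_frame(percent=percent).to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "p0": self.p0,
            "levels": {
                g: {"paf": e.paf, "lower": e.lower, "upper": e.upper}
                for g, e in self.entries.items()
            },
            "total": {
                "paf": self.total.paf,
                "lower": self.total.lower,
                "upper": self.total.upper,
            },
        }


def total_paf(
    case_fractions: CaseFractions | Mapping[str, float],
    risks: EstimateSet,
    p0: float | None = None,
) -> PafTable:
    """Multi-level PAF from case fractions and per-level risk ratios.

    The reference level contributes zero and is excluded from the sum.
    CIs re-evaluate every per-level PAF at the lower (upper) RR bounds and
    sum, so the total's bounds inherit only RR uncertainty.
    """
    fractions = (
        case_fractions.fractions
        if isinstance(case_fractions, CaseFractions)
        else dict(case_fractions)
    )
    risk_levels = set(risks.levels)
    frac_levels = set(fractions) - {risks.reference}
    if risk_levels != frac_levels:
        raise ValueError(
            f"exposure levels disagree: case fractions have {sorted(frac_levels)}, "
            f"risk estimates have {sorted(risk_levels)}"
        )

    entries: dict[str, PafEntry] = {}
    tot = lo_tot = hi_tot = 0.0
    for g in risks.levels:
        p_ci = fractions[g]
        e = risks[g]
        paf = genotype_paf(p_ci, e.point)
        lo = genotype_paf(p_ci, e.lower)
        hi = genotype_paf(p_ci, e.upper)
        entries[g] = PafEntry(paf, lo, hi)
        tot += paf
        lo_tot += lo
        hi_tot += hi
    return PafTable(
        entries=entries,
        total=PafEntry(tot, lo_tot, hi_tot),
        reference=risks.reference,
        p0=p0,
    )


def paf_from_points(
    per_level_paf: Mapping[str, float], reference: str = REFERENCE_GENOTYPE
) -> PafTable:
    """Aggregate already-computed per-level PAF point estimates (fractions)."""
    entries = {g: PafEntry(float(v)) for g, v in per_level_paf.items()}
    return PafTable(
        entries=entries,
        total=PafEntry(sum(e.paf for e in entries.values())),
        reference=reference,
    )


# ---------------------------------------------------------------------------
# Allele-wise partition
# ---------------------------------------------------------------------------

def _share_rr_proportional(rr_e23: float, rr_e24: float) -> float:
    return rr_e24 / (rr_e23 + rr_e24)


def _share_excess_rr_proportional(rr_e23: float, rr_e24: float) -> float:
    return (rr_e24 - 1.0) / ((rr_e23 - 1.0) + (rr_e24 - 1.0))


#: ε4 share of the ε3/ε4 genotype's PAF as a function of the single-allele
#: add-on genotypes' RRs (ε2/ε3 for ε3, ε2/ε4 for ε4).
PARTITION_RULES = {
    "rr-proportional": _share_rr_proportional,
    "excess-rr-proportional": _share_excess_rr_proportional,
}


@dataclass(frozen=True)
class AllelePartition:
    """Split of the five-genotype total PAF into ε3 and ε4 allele shares."""

    paf_e3: PafEntry
    paf_e4: PafEntry
    rule: str


def partition_alleles(
    pafs: PafTable, risks: EstimateSet, rule: str = "rr-proportional"
) -> AllelePartition:
    """Partition the total PAF into ε3- and ε4-attributable shares.

    Genotypes containing a single risk allele type are assigned wholly to
    that allele (ε2/ε3 and ε3/ε3 → ε3; ε2/ε4 and ε4/ε4 → ε4).  The mixed
    ε3/ε4 genotype's PAF is split between the alleles; under the default
    ``rr-proportional`` rule the ε4 weight is RR(ε2/ε4)/(RR(ε2/ε3)+RR(ε2/ε4)),
    i.e. proportional to the risk each allele confers when added to an ε2
    background.  ``excess-rr-proportional`` weights by RR−1 instead.  Either
    way the two shares sum exactly to the five-genotype total.
    """
    try:
        share_fn = PARTITION_RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown partition rule {rule!r}; available: {sorted(PARTITION_RULES)}"
        ) from None
    needed = {"e2/e3", "e3/e3", "e2/e4", "e3/e4", "e4/e4"}
    if not needed <= set(pafs.levels):
        raise ValueError("allele partition requires the five APOE risk genotypes")

    def _at(which: str) -> tuple[float, float]:
        """(ε3 total, ε4 total) using the point / lower / upper RRs."""
        def pafv(g: str) -> float:
            e = pafs[g]
            return {"point": e.paf, "lower": e.lower, "upper": e.upper}[which]

        def rrv(g: str) -> float:
            e = risks[g]
            return {"point": e.point, "lower": e.lower, "upper": e.upper}[which]

        w4 = share_fn(rrv("e2/e3"), rrv("e2/e4"))
        mixed = pafv("e3/e4")
        e3 = pafv("e2/e3") + pafv("e3/e3") + (1.0 - w4) * mixed
        e4 = pafv("e2/e4") + pafv("e4/e4") + w4 * mixed
        return e3, e4

    e3_pt, e4_pt = _at("point")
    has_ci = all(pafs[g].lower is not None for g in needed)
    if has_ci:
        e3_lo, e4_lo = _at("lower")
        e3_hi, e4_hi = _at("upper")
        return AllelePartition(
            PafEntry(e3_pt, e3_lo, e3_hi), PafEntry(e4_pt, e4_lo, e4_hi), rule
        )
    return AllelePartition(PafEntry(e3_pt), PafEntry(e4_pt), rule)


# ---------------------------------------------------------------------------
# Baseline-risk sensitivity
# ---------------------------------------------------------------------------

def sensitivity_p0(
    table: GenotypeCountTable,
    grid: Sequence[float],
    correction: bool = False,
) -> list[tuple[float, PafTable]]:
    """Total PAF as a function of the assumed baseline risk p0.

    Runs the full crude-OR → RR(p0) → PAF pipeline on a case-control count
    table for every p0 in the grid.  For ORs above one the conversion — and
    hence every PAF — is decreasing in p0, so the totals fall monotonically
    along an increasing grid.
    """
    ors = crude_or(table, correction=correction)
    fractions = CaseFractions.from_counts(table)
    out = []
    for p0 in grid:
        rrs = convert_or_set(ors, ConversionConfig(p0=p0))
        out.append((p0, total_paf(fractions, rrs, p0=p0)))
    return out
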