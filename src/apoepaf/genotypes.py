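"""APOE genotype coding from rs429358/rs7412 diplotypes, count tables, and HWE testing.

The three common APOE alleles are haplotypes of two SNPs:

====== ========= =======
allele rs429358  rs7412
====== ========= =======
ε2     T         T
ε3     T         C
ε4     C         C
(ε1    C         T — vanishingly rare, treated as missing)
====== ========= =======

An unphased diplotype (one unordered base pair per SNP) usually implies a
unique pair of haplotypes.  The double heterozygote rs429358 C/T +
rs7412 C/T is consistent with both ε2/ε4 and ε1/ε3; by default it is
assigned ε2/ε4 because ε1 is essentially absent from real populations.
Diplotypes that can only be explained with an ε1 haplotype are returned
as missing (``None``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "APOE_GENOTYPES",
    "REFERENCE_GENOTYPE",
    "RISK_GENOTYPES",
    "HAPLOTYPE_TO_ALLELE",
    "code_apoe",
    "diplotype_for_genotype",
    "carriage_flags",
    "carriage_counts",
    "hwe_test",
    "HweResult",
    "GenotypeCountTable",
]

#: Canonical ordering of the six unordered ε-allele pairs.  ε2/ε2 is the
#: lowest-risk genotype and serves as the reference level throughout.
APOE_GENOTYPES: tuple[str, ...] = (
    "e2/e2",
    "e2/e3",
    "e3/e3",
    "e2/e4",
    "e3/e4",
    "e4/e4",
)

REFERENCE_GENOTYPE = "e2/e2"

#: The five risk-increasing genotypes, in canonical order.
RISK_GENOTYPES: tuple[str, ...] = tuple(
    g for g in APOE_GENOTYPES if g != REFERENCE_GENOTYPE
)

#: (rs429358 allele, rs7412 allele) -> ε allele.
HAPLOTYPE_TO_ALLELE: dict[tuple[str, str], str] = {
    ("T", "T"): "e2",
    ("T", "C"): "e3",
    ("C", "C"): "e4",
    ("C", "T"): "e1",
}

_ALLELE_SETS = {"rs429358": {"T", "C"}, "rs7412": {"C", "T"}}


def normalize_genotype(g: str) -> str:
    """Normalise a genotype label to canonical ASCII, order-insensitive.

    Accepts e.g. ``"ε4/ε3"``, ``"e3/e4"``, ``"E3/E4"`` -> ``"e3/e4"``.
    """
    s = g.strip().lower().replace("ε", "e")
    parts = s.split("/")
    if len(parts) != 2 or not all(p in {"e1", "e2", "e3", "e4"} for p in parts):
        raise ValueError(f"unrecognised APOE genotype label: {g!r}")
    a, b = sorted(parts)
    return f"{a}/{b}"


def _parse_diplotype(snp: str, value: str) -> tuple[str, str]:
    alleles = tuple(value.strip().upper().replace("/", ""))
    if len(alleles) != 2 or any(a not in _ALLELE_SETS[snp] for a in alleles):
        raise ValueError(
            f"invalid diplotype {value!r} at {snp}: expected two alleles "
            f"from {sorted(_ALLELE_SETS[snp])}"
        )
    return alleles  # type: ignore[return-value]


def code_apoe(
    rs429358: str,
    rs7412: str,
    ambiguity_policy: str = "e2/e4",
) -> str | None:
    """Translate a two-SNP diplotype into an APOE ε-genotype.

    Parameters
    ----------
    rs429358, rs7412
        Unordered base pairs, e.g. ``"CT"`` or ``"T/T"``.  Allele order
        within a pair carries no meaning.
    ambiguity_policy
        How to resolve the phase-ambiguous double heterozygote
        (rs429358 C/T with rs7412 C/T): ``"e2/e4"`` (default) assigns
        ε2/ε4; ``"missing"`` returns ``None``.

    Returns
    -------
    The canonical genotype string, or ``None`` for diplotypes that imply
    an ε1 haplotype (these individuals are excluded, not errors).
    """
    if ambiguity_policy not in {"e2/e4", "missing"}:
        raise ValueError(f"unknown ambiguity_policy: {ambiguity_policy!r}")
    a = _parse_diplotype("rs429358", rs429358)
    b = _parse_diplotype("rs7412", rs7412)

    # Two possible phasings of the unordered pairs.
    phasings = {
        tuple(sorted((HAPLOTYPE_TO_ALLELE[(a[0], b[0])], HAPLOTYPE_TO_ALLELE[(a[1], b[1])]))),
        tuple(sorted((HAPLOTYPE_TO_ALLELE[(a[0], b[1])], HAPLOTYPE_TO_ALLELE[(a[1], b[0])]))),
    }
    valid = [p for p in phasings if "e1" not in p]
    if not valid:
        return None
    if len(phasings) > 1 and len(valid) == 1 and valid[0] == ("e2", "e4"):
        # The C/T + C/T double heterozygote: {ε2,ε4} vs {ε1,ε3}.
        if ambiguity_policy == "missing":
            return None
    h1, h2 = valid[0]
    return f"{h1}/{h2}"


#: Inverse coding: genotype -> (rs429358 diplotype, rs7412 diplotype).
#: For ε2/ε4 this deliberately emits the ambiguous double heterozygote.
_ALLELE_TO_HAPLOTYPE = {v: k for k, v in HAPLOTYPE_TO_ALLELE.items()}


def diplotype_for_genotype(genotype: str) -> tuple[str, str]:
    """Return the (rs429358, rs7412) diplotype strings implied by a genotype."""
    g = normalize_genotype(genotype)
    a1, a2 = g.split("/")
    h1, h2 = _ALLELE_TO_HAPLOTYPE[a1], _ALLELE_TO_HAPLOTYPE[a2]
    return "".join(sorted((h1[0], h2[0]))), "".join(sorted((h1[1], h2[1])))


def carriage_flags(genotype: str) -> dict[str, bool]:
    """Flags for whether each ε allele appears in the genotype.

    Carriage groups overlap: an ε2/ε4 individual carries both ε2 and ε4.
    """
    g = normalize_genotype(genotype)
    alleles = set(g.split("/"))
    return {f"carries_{a}": a in alleles for a in ("e2", "e3", "e4")}


def carriage_counts(counts: Mapping[str, int]) -> dict[str, int]:
    """Per-allele carriage counts from six-genotype counts (overlapping groups)."""
    out = {"e2": 0, "e3": 0, "e4": 0}
    for g, n in counts.items():
        flags = carriage_flags(g)
        for a in out:
            if flags[f"carries_{a}"]:
                out[a] += int(n)
    return out


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    df: int
    p: float
    allele_freqs: dict[str, float]
    expected: dict[str, float]


def hwe_test(counts: Mapping[str, int]) -> HweResult:
    """Chi-square test of triallelic Hardy–Weinberg equilibrium.

    Allele frequencies are estimated from the six genotype counts; the
    expected counts are the HWE expansion N·(f_i², 2f_i f_j); the statistic
    is Pearson's Σ(O−E)²/E on six classes with df = 6 − 1 − 2 = 3 (two free
    allele frequencies are estimated from the data).
    """
    obs = {normalize_genotype(g): int(n) for g, n in counts.items()}
    missing = set(APOE_GENOTYPES) - set(obs)
    if missing:
        raise ValueError(f"counts missing genotypes: {sorted(missing)}")
    n_total = sum(obs.values())
    if n_total <= 0:
        raise ValueError("total genotype count must be positive")

    freqs = {}
    for allele in ("e2", "e3", "e4"):
        n_copies = sum(
            n * g.split("/").count(allele) for g, n in obs.items()
        )
        freqs[allele] = n_copies / (2 * n_total)

    expected: dict[str, float] = {}
    for g in APOE_GENOTYPES:
        a1, a2 = g.split("/")
        if a1 == a2:
            expected[g] = n_total * freqs[a1] ** 2
        else:
            expected[g] = n_total * 2 * freqs[a1] * freqs[a2]

    chi2 = sum(
        (obs[g] - expected[g]) ** 2 / expected[g]
        for g in APOE_GENOTYPES
        if expected[g] > 0
    )
    df = 3
    return HweResult(
        chi_square=float(chi2),
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        allele_freqs=freqs,
        expected=expected,
    )


@dataclass(frozen=True)
class GenotypeCountTable:
    """Outcome counts per exposure level.

    For a ``cohort`` design, ``denominators`` holds per-level totals (cases
    are a subset); for a ``case-control`` design it holds control counts
    (disjoint from cases).  Levels are usually the six APOE genotypes but
    may be any exposure coding (e.g. the two-level ε2/ε2 vs carrier split).
    """

    cases: Mapping[str, int]
    denominators: Mapping[str, int]
    design: str  # "cohort" | "case-control"
    reference: str = REFERENCE_GENOTYPE

    def __post_init__(self) -> None:
        if self.design not in {"cohort", "case-control"}:
            raise ValueError(f"unknown design: {self.design!r}")
        if set(self.cases) != set(self.denominators):
            raise ValueError("cases and denominators must share the same levels")
        if self.reference not in self.cases:
            raise ValueError(f"reference level {self.reference!r} not in table")
        for level in self.cases:
            c, d = int(self.cases[level]), int(self.denominators[level])
            if c < 0 or d < 0:
                raise ValueError(f"negative count at level {level!r}")
            if self.design == "cohort" and c > d:
                raise ValueError(f"cases exceed total at level {level!r}")

    # -- convenience constructors -------------------------------------
    @classmethod
    def from_cohort(
        cls, cases: Mapping[str, int], totals: Mapping[str, int], reference: str = REFERENCE_GENOTYPE
    ) -> "GenotypeCountTable":
        return cls(cases=dict(cases), denominators=dict(totals), design="cohort", reference=reference)

    @classmethod
    def from_case_control(
        cls, cases: Mapping[str, int], controls: Mapping[str, int], reference: str = REFERENCE_GENOTYPE
    ) -> "GenotypeCountTable":
        return cls(cases=dict(cases), denominators=dict(controls), design="case-control", reference=reference)

    # -- accessors ----------------------------------------------------
    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.cases)

    @property
    def controls(self) -> Mapping[str, int]:
        if self.design != "case-control":
            raise AttributeError("controls only defined for case-control design")
        return self.denominators

    @property
    def totals(self) -> Mapping[str, int]:
        if self.design != "cohort":
            raise AttributeError("totals only defined for cohort design")
        return self.denominators

    @property
    def n_cases(self) -> int:
        return int(sum(self.cases.values()))

    def case_fractions(self) -> dict[str, float]:
        """Fraction of all cases in each level (sums to 1 across levels)."""
        n = self.n_cases
        if n == 0:
            raise ValueError("no cases in table")
        return {g: self.cases[g] / n for g in self.levels}

    def to_frame(self) -> pd.DataFrame:
        col = "controls" if self.design == "case-control" else "totals"
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "cases": [self.cases[g] for g in self.levels],
                col: [self.denominators[g] for g in self.levels],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, reference: str = REFERENCE_GENOTYPE) -> "GenotypeCountTable":
        df = pd.read_csv(path, sep="\t")
        if "controls" in df.columns:
            return cls.from_case_control(
                dict(zip(df["level"], df["cases"])),
                dict(zip(df["level"], df["controls"])),
                reference=reference,
            )
        if "totals" in df.columns:
            return cls.from_cohort(
                dict(zip(df["level"], df["cases"])),
                dict(zip(df["level"], df["totals"])),
                reference=reference,
            )
        raise ValueError("count TSV needs a 'controls' or 'totals' column")


def tabulate_cohort(
    cohort: pd.DataFrame, outcome: str = "outcome", genotype: str = "genotype"
) -> GenotypeCountTable:
    """Tabulate an individual-level cohort into a cohort-design count table."""
    grouped = cohort.groupby(genotype)[outcome]
    cases = grouped.sum().astype(int).to_dict()
    totals = grouped.size().astype(int).to_dict()
    for g in APOE_GENOTYPES:
        cases.setdefault(g, 0)
        totals.setdefault(g, 0)
    cases = {g: cases[g] for g in APOE_GENOTYPES}
    totals = {g: totals[g] for g in APOE_GENOTYPES}
    return GenotypeCountTable.from_cohort(cases, totals)
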