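"""Attributable fractions for arbitrary biallelic GWAS loci.

From a risk-allele frequency and a per-allele odds ratio, the three
genotype classes (0, 1, 2 copies of the risk allele) get HWE frequencies
(1−f)², 2f(1−f), f² and odds ratios (1, OR, OR²) under the multiplicative
model — or (1, OR, OR) under a dominant / carrier coding.  ORs are
converted to risk ratios at an assumed baseline risk p0 in the zero-copy
genotype, implied case fractions follow as q_i·RR_i/Σ q_j·RR_j, and the
multi-level PAF formula applies.

Because real GWAS report case fractions only in their own samples, the
case fractions here are the ones implied by HWE and the model — a
modelling construction recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .paf import genotype_paf
from .risk import ConversionConfig, or_to_rr

__all__ = ["LocusSummary", "LocusPaf", "locus_paf", "rank_loci", "read_loci_tsv", "loci_frame"]

_MODELS = {"multiplicative", "dominant"}


@dataclass(frozen=True)
class LocusSummary:
    """GWAS summary row: locus id, risk-allele frequency, per-allele OR."""

    locus_id: str
    risk_allele_freq: float
    odds_ratio: float
    model: str = "multiplicative"
    p0: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.risk_allele_freq <= 1):
            raise ValueError("risk allele frequency must lie in [0, 1]")
        if not (self.odds_ratio > 0):
            raise ValueError("odds ratio must be positive")
        if self.model not in _MODELS:
            raise ValueError(f"unknown genetic model {self.model!r}; use {sorted(_MODELS)}")
        ConversionConfig(p0=self.p0)  # validates


@dataclass(frozen=True)
class LocusPaf:
    locus_id: str
    paf: float
    model: str
    p0: float
    genotype_freqs: tuple[float, float, float]
    genotype_rrs: tuple[float, float, float]
    case_fractions: tuple[float, float, float]
    genotype_pafs: tuple[float, float, float]
    case_fraction_source: str = "hwe-implied"


def locus_paf(locus: LocusSummary) -> LocusPaf:
    """Multi-level PAF attributable to one biallelic locus."""
    f = locus.risk_allele_freq
    q = ((1 - f) ** 2, 2 * f * (1 - f), f**2)
    if locus.model == "multiplicative":
        ors = (1.0, locus.odds_ratio, locus.odds_ratio**2)
    else:  # dominant / carrier coding
        ors = (1.0, locus.odds_ratio, locus.odds_ratio)
    cfg = ConversionConfig(p0=locus.p0)
    rrs = tuple(or_to_rr(o, cfg) for o in ors)
    denom = sum(qi * ri for qi, ri in zip(q, rrs))
    p_c = tuple(qi * ri / denom for qi, ri in zip(q, rrs))
    pafs = tuple(genotype_paf(pc, rr) for pc, rr in zip(p_c, rrs))
    return LocusPaf(
        locus_id=locus.locus_id,
        paf=sum(pafs[1:]),  # zero-copy genotype is the reference
        model=locus.model,
        p0=locus.p0,
        genotype_freqs=q,
        genotype_rrs=rrs,
        case_fractions=p_c,
        genotype_pafs=pafs,
    )


def rank_loci(loci: Sequence[LocusSummary], top_k: int | None = None) -> list[LocusPaf]:
    """Rank loci by PAF, descending; ties broken by locus id (ascending)."""
    if not loci:
        raise ValueError("empty locus list")
    results = [locus_paf(l) for l in loci]
    results.sort(key=lambda r: (-r.paf, r.locus_id))
    return results if top_k is None else results[:top_k]


def read_loci_tsv(path, p0: float = 0.01) -> list[LocusSummary]:
    """Read loci from TSV with columns locus_id, eaf, or[, model[, p0]]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            LocusSummary(
                locus_id=str(row["locus_id"]),
                risk_allele_freq=float(row["eaf"]),
                odds_ratio=float(row["or"]),
                model=str(row.get("model", "multiplicative"))
                if "model" in df.columns
                else "multiplicative",
                p0=float(row["p0"]) if "p0" in df.columns else p0,
            )
        )
    return out


def loci_frame(results: Sequence[LocusPaf], percent: bool = True) -> pd.DataFrame:
    scale = 100.0 if percent else 1.0
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in results],
            "paf": [r.paf * scale for r in results],
            "model": [r.model for r in results],
            "p0": [r.p0 for r in results],
            "case_fraction_source": [r.case_fraction_source for r in results],
        }
    )
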