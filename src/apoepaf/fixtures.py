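"""Embedded published count tables and risk estimates.

The in-text datasets the reproduction recipes run on: APOE genotype counts
for the ADGC neuropathology case-control sample and the A4 amyloid-PET
screening sample, per-genotype risk ratios (with 95% CIs) published for
the UK Biobank, FinnGen, A4 and ADGC analyses, and the FinnGen
per-genotype PAF point estimates.  All values are transcribed from the
source publication's tables; an integrity digest guards against silent
edits.
"""

from __future__ import annotations

import hashlib
import json

from .genotypes import GenotypeCountTable
from .risk import RiskEstimateSet

__all__ = [
    "ADGC_COUNTS",
    "A4_CARRIER_COUNTS",
    "UKB_GENOTYPE_COUNTS",
    "ADGC_RRS",
    "UKB_RRS",
    "FINNGEN_RRS",
    "A4_RRS",
    "FINNGEN_AD_PAF_PERCENT",
    "SUVR_POSITIVITY_THRESHOLD",
    "verify_fixtures",
]

# ADGC neuropathologically confirmed AD case-control sample:
# 4018 cases, 989 controls.
ADGC_COUNTS = GenotypeCountTable.from_case_control(
    cases={
        "e2/e2": 5,
        "e2/e3": 113,
        "e3/e3": 1273,
        "e2/e4": 107,
        "e3/e4": 1897,
        "e4/e4": 623,
    },
    controls={
        "e2/e2": 19,
        "e2/e3": 147,
        "e3/e3": 638,
        "e2/e4": 20,
        "e3/e4": 155,
        "e4/e4": 10,
    },
)

# A4 screening sample, two-level split: amyloid-β positives among the 25
# ε2/ε2 homozygotes vs the 4390 ε3/ε4-allele carriers (4415 total, 1203 Aβ+).
A4_CARRIER_COUNTS = GenotypeCountTable.from_cohort(
    cases={"e2/e2": 1, "carrier": 1202},
    totals={"e2/e2": 25, "carrier": 4390},
)

# UK Biobank full analytical sample (ages 60+), genotype counts.
UKB_GENOTYPE_COUNTS = {
    "e2/e2": 1047,
    "e2/e3": 21018,
    "e3/e3": 100826,
    "e2/e4": 4208,
    "e3/e4": 39974,
    "e4/e4": 4032,
}

# Published per-genotype risk ratios (point, lower, upper) vs ε2/ε2.
ADGC_RRS = RiskEstimateSet.from_table(
    {
        "e2/e3": (2.94, 1.38, 5.71),
        "e3/e3": (7.21, 2.73, 16.81),
        "e2/e4": (17.23, 4.42, 46.83),
        "e3/e4": (32.26, 12.48, 59.95),
        "e4/e4": (70.81, 31.76, 92.23),
    },
    provenance="published (ADGC, neuropathologically confirmed AD)",
)

UKB_RRS = RiskEstimateSet.from_table(
    {
        "e2/e3": (1.68, 0.69, 4.07),
        "e3/e3": (2.19, 0.91, 5.25),
        "e2/e4": (4.03, 1.64, 9.91),
        "e3/e4": (8.39, 3.50, 20.13),
        "e4/e4": (23.36, 9.71, 56.19),
    },
    provenance="published (UK Biobank, AD)",
)

FINNGEN_RRS = RiskEstimateSet.from_table(
    {
        "e2/e3": (1.63, 1.00, 2.63),
        "e3/e3": (2.29, 1.40, 3.71),
        "e2/e4": (4.44, 2.87, 6.79),
        "e3/e4": (6.37, 4.32, 9.25),
        "e4/e4": (9.79, 7.44, 12.73),
    },
    provenance="published (FinnGen, AD)",
)

A4_RRS = RiskEstimateSet.from_table(
    {
        "e2/e3": (3.30, 0.48, 13.21),
        "e3/e3": (4.27, 0.64, 14.88),
        "e2/e4": (8.36, 1.42, 19.58),
        "e3/e4": (12.39, 2.80, 21.89),
        "e4/e4": (20.32, 8.67, 24.24),
    },
    provenance="published (A4, amyloid-β positivity)",
)

# FinnGen per-genotype AD PAF point estimates, percent.
FINNGEN_AD_PAF_PERCENT = {
    "e2/e3": 1.6,
    "e3/e3": 22.7,
    "e2/e4": 1.9,
    "e3/e4": 35.6,
    "e4/e4": 9.7,
}

#: Amyloid PET standardised uptake value ratio cut-off defining Aβ+ in A4.
SUVR_POSITIVITY_THRESHOLD = 1.15


def _digest() -> str:
    payload = {
        "adgc_cases": dict(ADGC_COUNTS.cases),
        "adgc_controls": dict(ADGC_COUNTS.controls),
        "a4_cases": dict(A4_CARRIER_COUNTS.cases),
        "a4_totals": dict(A4_CARRIER_COUNTS.totals),
        "ukb_counts": UKB_GENOTYPE_COUNTS,
        "adgc_rrs": {g: (e.point, e.lower, e.upper) for g, e in ADGC_RRS.estimates.items()},
        "ukb_rrs": {g: (e.point, e.lower, e.upper) for g, e in UKB_RRS.estimates.items()},
        "finngen_rrs": {g: (e.point, e.lower, e.upper) for g, e in FINNGEN_RRS.estimates.items()},
        "a4_rrs": {g: (e.point, e.lower, e.upper) for g, e in A4_RRS.estimates.items()},
        "finngen_pafs": FINNGEN_AD_PAF_PERCENT,
        "suvr": SUVR_POSITIVITY_THRESHOLD,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


_EXPECTED_DIGEST = "ecc2dce151846a9a47bdb725ee58bb5c999578edff10b43cd4962003309310f4"


def verify_fixtures() -> str:
    """Hash-check the embedded tables against the frozen transcription digest."""
    d = _digest()
    if d != _EXPECTED_DIGEST:
        raise RuntimeError(
            f"fixture digest mismatch: {d} != {_EXPECTED_DIGEST}; "
            "the embedded published values have been altered"
        )
    return d
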