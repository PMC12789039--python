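"""Synthetic individual-level cohorts with known genotype risks.

Generates subject-level tables (sample id, two SNP diplotypes, APOE
genotype, age, sex, binary outcome) from a fully specified generative
model, so the coding → risk-estimation → PAF pipeline can be validated
against closed-form truth without access to any real biobank.

The outcome model is multiplicative on the risk scale:

    P(outcome | genotype i, age, sex) = p0 · RR_i · exp(β_age·(age−μ_age) + β_sex·sex)

with p0 the baseline risk in ε2/ε2 and RR_i the genotype risk ratio.
Parameter sets whose implied maximum risk exceeds one are rejected at
construction.  With zero covariate effects the generative total PAF has
the closed form implemented in :func:`true_paf`.

Three sampling designs are supported: plain cohort; case-control with
fixed case and control quotas (rejection-sampled from the cohort model);
and a screened design in which affected subjects are retained with a
genotype-specific probability — a volunteer/screening mechanism that
depletes cases preferentially in high-risk genotypes and therefore biases
their estimated risk ratios toward the null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import (
    APOE_GENOTYPES,
    REFERENCE_GENOTYPE,
    diplotype_for_genotype,
    normalize_genotype,
)
from .paf import PafEntry, PafTable

__all__ = ["CohortParams", "generate_cohort", "true_paf", "write_cohort", "hwe_genotype_freqs"]

# UK Biobank-scale genotype distribution (ages 60+, N = 171,105): the
# default population the generator emulates.
_DEFAULT_GENOTYPE_FREQS = {
    "e2/e2": 1047 / 171105,
    "e2/e3": 21018 / 171105,
    "e3/e3": 100826 / 171105,
    "e2/e4": 4208 / 171105,
    "e3/e4": 39974 / 171105,
    "e4/e4": 4032 / 171105,
}

# Default genotype risk ratios: the AD gradient estimated at biobank scale
# (ε2/ε3 1.68 … ε4/ε4 23.36 against ε2/ε2).
_DEFAULT_GENOTYPE_RR = {
    "e2/e2": 1.0,
    "e2/e3": 1.68,
    "e3/e3": 2.19,
    "e2/e4": 4.03,
    "e3/e4": 8.39,
    "e4/e4": 23.36,
}

#: Age span (SDs around the mean) used when validating that covariate
#: effects cannot push any individual risk above one.
_AGE_VALIDATION_SDS = 4.0


def hwe_genotype_freqs(allele_freqs: Mapping[str, float]) -> dict[str, float]:
    """Expand ε2/ε3/ε4 allele frequencies into HWE genotype frequencies."""
    f = {normalize_genotype(f"{a}/{a}").split("/")[0]: float(p) for a, p in allele_freqs.items()}
    if abs(sum(f.values()) - 1.0) > 1e-9 or any(v < 0 for v in f.values()):
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    out = {}
    for g in APOE_GENOTYPES:
        a1, a2 = g.split("/")
        out[g] = f[a1] ** 2 if a1 == a2 else 2 * f[a1] * f[a2]
    return out


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for a synthetic cohort.

    ``sampling`` is one of ``"cohort"``, ``"case-control"`` (uses
    ``n_cases``/``n_controls``) or ``"screened"`` (uses
    ``screening_inclusion``, a per-genotype retention probability applied
    to affected subjects).
    """

    n: int = 10_000
    genotype_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GENOTYPE_FREQS)
    )
    baseline_risk: float = 0.01
    genotype_rr: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GENOTYPE_RR)
    )
    age_mean: float = 64.1
    age_sd: float = 2.8
    beta_age: float = 0.0
    beta_sex: float = 0.0
    seed: int = 0
    sampling: str = "cohort"
    n_cases: int | None = None
    n_controls: int | None = None
    screening_inclusion: Mapping[str, float] | None = None

    @classmethod
    def from_allele_freqs(cls, allele_freqs: Mapping[str, float], **kwargs) -> "CohortParams":
        return cls(genotype_freqs=hwe_genotype_freqs(allele_freqs), **kwargs)

    def __post_init__(self) -> None:
        freqs = {normalize_genotype(g): float(p) for g, p in self.genotype_freqs.items()}
        object.__setattr__(self, "genotype_freqs", freqs)
        rrs = {normalize_genotype(g): float(r) for g, r in self.genotype_rr.items()}
        rrs.setdefault(REFERENCE_GENOTYPE, 1.0)
        object.__setattr__(self, "genotype_rr", rrs)

        if set(freqs) != set(APOE_GENOTYPES):
            raise ValueError("genotype_freqs must cover the six APOE genotypes")
        if any(p < 0 for p in freqs.values()) or abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError("genotype frequencies must be non-negative and sum to 1")
        if not (0 < self.baseline_risk < 1):
            raise ValueError("baseline_risk must lie in (0, 1)")
        if set(rrs) != set(APOE_GENOTYPES):
            raise ValueError("genotype_rr must cover the six APOE genotypes")
        if any(r <= 0 for r in rrs.values()):
            raise ValueError("risk ratios must be positive")
        if abs(rrs[REFERENCE_GENOTYPE] - 1.0) > 1e-12:
            raise ValueError("the reference genotype's RR must be 1")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.sampling not in {"cohort", "case-control", "screened"}:
            raise ValueError(f"unknown sampling design: {self.sampling!r}")
        if self.sampling == "case-control" and not (self.n_cases and self.n_controls):
            raise ValueError("case-control sampling needs n_cases and n_controls")
        if self.sampling == "screened":
            inc = self.screening_inclusion
            if inc is None:
                raise ValueError("screened sampling needs screening_inclusion")
            inc = {normalize_genotype(g): float(v) for g, v in inc.items()}
            if set(inc) != set(APOE_GENOTYPES) or any(not (0 <= v <= 1) for v in inc.values()):
                raise ValueError(
                    "screening_inclusion must give each genotype a probability in [0, 1]"
                )
            object.__setattr__(self, "screening_inclusion", inc)

        max_cov = np.exp(
            abs(self.beta_age) * _AGE_VALIDATION_SDS * self.age_sd + abs(self.beta_sex)
        )
        max_risk = self.baseline_risk * max(rrs.values()) * max_cov
        if max_risk > 1:
            raise ValueError(
                f"parameter set implies individual risk up to {max_risk:.3f} > 1; "
                "lower baseline_risk, the largest RR, or the covariate effects"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genotype_freqs"] = dict(self.genotype_freqs)
        d["genotype_rr"] = dict(self.genotype_rr)
        if self.screening_inclusion is not None:
            d["screening_inclusion"] = dict(self.screening_inclusion)
        return d


def _simulate_block(params: CohortParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    genotypes = rng.choice(
        APOE_GENOTYPES, size=n, p=[params.genotype_freqs[g] for g in APOE_GENOTYPES]
    )
    age = rng.normal(params.age_mean, params.age_sd, size=n)
    sex = rng.integers(0, 2, size=n)
    rr = np.array([params.genotype_rr[g] for g in genotypes])
    risk = (
        params.baseline_risk
        * rr
        * np.exp(params.beta_age * (age - params.age_mean) + params.beta_sex * sex)
    )
    # The validation bound uses a finite age span; clip the residual tail.
    risk = np.minimum(risk, 1.0)
    outcome = (rng.random(n) < risk).astype(int)
    dip = [diplotype_for_genotype(g) for g in genotypes]
    return pd.DataFrame(
        {
            "rs429358": [d[0] for d in dip],
            "rs7412": [d[1] for d in dip],
            "genotype": genotypes,
            "age": np.round(age, 3),
            "sex": sex,
            "outcome": outcome,
        }
    )


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a subject table under the given generative parameters.

    Returns a DataFrame with columns sample_id, rs429358, rs7412,
    genotype, age, sex, outcome.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)

    if params.sampling == "cohort":
        df = _simulate_block(params, params.n, rng)

    elif params.sampling == "screened":
        df = _simulate_block(params, params.n, rng)
        inc = params.screening_inclusion
        keep_p = np.where(
            df["outcome"].to_numpy() == 1,
            np.array([inc[g] for g in df["genotype"]]),
            1.0,
        )
        df = df[rng.random(len(df)) < keep_p].reset_index(drop=True)

    else:  # case-control with fixed quotas
        need_cases, need_controls = int(params.n_cases), int(params.n_controls)
        cases, controls = [], []
        got_cases = got_controls = 0
        # Rejection-sample from the cohort model in batches; batch size is
        # scaled to the rarer arm's expected yield.
        exp_rate = params.baseline_risk * sum(
            params.genotype_freqs[g] * params.genotype_rr[g] for g in APOE_GENOTYPES
        )
        exp_rate = min(max(exp_rate, 1e-6), 1 - 1e-6)
        for _ in range(1000):
            if got_cases >= need_cases and got_controls >= need_controls:
                break
            deficit = max(
                (need_cases - got_cases) / exp_rate,
                (need_controls - got_controls) / (1 - exp_rate),
            )
            batch = _simulate_block(params, int(np.ceil(deficit * 1.2)) + 100, rng)
            new_cases = batch[batch["outcome"] == 1]
            new_controls = batch[batch["outcome"] == 0]
            cases.append(new_cases.iloc[: need_cases - got_cases])
            controls.append(new_controls.iloc[: need_controls - got_controls])
            got_cases += len(cases[-1])
            got_controls += len(controls[-1])
        if got_cases < need_cases or got_controls < need_controls:
            raise RuntimeError("case-control rejection sampling failed to fill quotas")
        df = pd.concat(cases + controls, ignore_index=True)

    df.insert(0, "sample_id", [f"S{i:07d}" for i in range(len(df))])
    return df


def true_paf(params: CohortParams) -> PafTable:
    """Closed-form total PAF implied by the generative parameters.

    Under the multiplicative model with covariate effects averaging out,
    the expected case fraction of genotype i is
    p_ci = q_i·RR_i / Σ_j q_j·RR_j, and PAF_i = p_ci·(RR_i−1)/RR_i.
    """
    q = params.genotype_freqs
    rr = params.genotype_rr
    denom = sum(q[g] * rr[g] for g in APOE_GENOTYPES)
    entries = {}
    total = 0.0
    for g in APOE_GENOTYPES:
        if g == REFERENCE_GENOTYPE:
            continue
        p_ci = q[g] * rr[g] / denom
        paf = p_ci * (rr[g] - 1.0) / rr[g]
        entries[g] = PafEntry(paf)
        total += paf
    return PafTable(entries=entries, total=PafEntry(total), p0=params.baseline_risk)


def write_cohort(df: pd.DataFrame, path, params: CohortParams | None = None) -> None:
    """Write a cohort TSV; alongside it, a JSON provenance sidecar of the
    generative parameters (including the seed) when given."""
    df.to_csv(path, sep="\t", index=False)
    if params is not None:
        sidecar = str(path) + ".params.json"
        with open(sidecar, "w") as fh:
            json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
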