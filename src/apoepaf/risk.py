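"""Relative-risk and odds-ratio estimation against the ε2/ε2 reference.

Provides crude contingency-table estimators with Wald (log-scale) confidence
intervals, re-orientation of odds ratios to a new reference level, the
baseline-risk odds-to-risk conversion RR = OR / (1 − p0 + p0·OR), and
individual-level log-binomial and logistic model fits (via statsmodels GLM).

Log-binomial models estimate risk ratios directly but can fail to converge
when fitted outcome probabilities approach one; in that case this module
raises :class:`ConvergenceError` with a diagnostic suggesting the logistic
regression + OR→RR conversion path, rather than silently switching models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotypes import GenotypeCountTable, REFERENCE_GENOTYPE

__all__ = [
    "Estimate",
    "EstimateSet",
    "OddsRatioSet",
    "RiskEstimateSet",
    "ConversionConfig",
    "ConvergenceError",
    "crude_rr",
    "crude_or",
    "reorient_or",
    "or_to_rr",
    "convert_or_set",
    "fit_log_binomial",
    "fit_logistic",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    """Model fit failed to converge or produced an invalid solution."""


@dataclass(frozen=True)
class Estimate:
    """A ratio estimate (RR or OR) with a 95% confidence interval."""

    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.point > 0):
            raise ValueError(f"ratio estimate must be positive, got {self.point}")
        if not (self.lower <= self.point <= self.upper):
            raise ValueError(
                f"CI must bracket the point estimate: "
                f"({self.lower}, {self.point}, {self.upper})"
            )


@dataclass(frozen=True)
class EstimateSet:
    """Per-level ratio estimates relative to a reference level.

    The reference level's implicit ratio is 1 and is not stored.
    ``provenance`` records how the estimates were obtained, e.g.
    ``"crude"``, ``"log-binomial"``, ``"logistic"``, ``"published"``,
    ``"converted-from-or(p0=0.01)"``.
    """

    estimates: Mapping[str, Estimate]
    reference: str = REFERENCE_GENOTYPE
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.reference in self.estimates:
            raise ValueError("reference level must not appear among estimates")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.estimates)

    def __getitem__(self, level: str) -> Estimate:
        return self.estimates[level]

    def points(self) -> dict[str, float]:
        return {g: e.point for g, e in self.estimates.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "estimate": [self.estimates[g].point for g in self.levels],
                "lower": [self.estimates[g].lower for g in self.levels],
                "upper": [self.estimates[g].upper for g in self.levels],
                "reference": self.reference,
                "provenance": self.provenance,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(
        cls,
        rows: Mapping[str, tuple[float, float, float]],
        reference: str = REFERENCE_GENOTYPE,
        provenance: str = "published",
    ) -> "EstimateSet":
        return cls(
            estimates={g: Estimate(*v) for g, v in rows.items()},
            reference=reference,
            provenance=provenance,
        )


# The two set flavours share all behaviour; the distinct names keep the
# RR-vs-OR scale explicit at call sites.
class RiskEstimateSet(EstimateSet):
    pass


class OddsRatioSet(EstimateSet):
    pass


@dataclass(frozen=True)
class ConversionConfig:
    """Baseline outcome probability p0 in the reference level, used by
    the OR→RR conversion."""

    p0: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1):
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")


# ---------------------------------------------------------------------------
# Crude contingency estimators
# ---------------------------------------------------------------------------

def _wald_ci(log_point: float, se: float) -> tuple[float, float]:
    return math.exp(log_point - _Z95 * se), math.exp(log_point + _Z95 * se)


def crude_rr(table: GenotypeCountTable, correction: bool = False) -> RiskEstimateSet:
    """Crude risk ratios from a cohort-design count table.

    RR_i = (cases_i/total_i) / (cases_ref/total_ref), Wald CI on the log
    scale with SE² = 1/a − 1/n1 + 1/b − 1/n0.  With ``correction``, 0.5 is
    added to zero case cells (Haldane–Anscombe); off by default.
    """
    if table.design != "cohort":
        raise ValueError("crude_rr requires a cohort-design table")
    ref = table.reference
    b, n0 = float(table.cases[ref]), float(table.totals[ref])
    if n0 <= 0:
        raise ValueError("reference level has zero total")
    if b == 0:
        if not correction:
            raise ZeroDivisionError(
                f"zero cases in reference level {ref!r}; enable the 0.5 "
                "continuity correction or choose another reference"
            )
        b += 0.5

    out: dict[str, Estimate] = {}
    for g in table.levels:
        if g == ref:
            continue
        a, n1 = float(table.cases[g]), float(table.totals[g])
        if n1 <= 0:
            raise ValueError(f"zero total at level {g!r}")
        if a == 0:
            if not correction:
                raise ZeroDivisionError(
                    f"zero cases at level {g!r}; enable the continuity correction"
                )
            a += 0.5
        rr = (a / n1) / (b / n0)
        se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n0)
        lo, hi = _wald_ci(math.log(rr), se)
        out[g] = Estimate(rr, lo, hi)
    return RiskEstimateSet(estimates=out, reference=ref, provenance="crude")


def crude_or(table: GenotypeCountTable, correction: bool = False) -> OddsRatioSet:
    """Crude odds ratios from a case-control count table.

    OR_i = (cases_i/cases_ref) / (controls_i/controls_ref), Wald log-scale
    CI with SE² = 1/a + 1/b + 1/c + 1/d.  Zero cells raise an error naming
    the cell unless the 0.5 continuity correction is enabled.
    """
    if table.design != "case-control":
        raise ValueError("crude_or requires a case-control table")
    ref = table.reference
    out: dict[str, Estimate] = {}
    for g in table.levels:
        if g == ref:
            continue
        cells = {
            f"cases[{g}]": float(table.cases[g]),
            f"controls[{g}]": float(table.controls[g]),
            f"cases[{ref}]": float(table.cases[ref]),
            f"controls[{ref}]": float(table.controls[ref]),
        }
        zero = [name for name, v in cells.items() if v == 0]
        if zero and not correction:
            raise ZeroDivisionError(
                f"zero cell(s) {zero} in the {g} vs {ref} 2x2 table; "
                "enable the 0.5 continuity correction to proceed"
            )
        a, c, b, d = (v + (0.5 if correction and zero else 0.0) for v in cells.values())
        or_ = (a / b) / (c / d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = _wald_ci(math.log(or_), se)
        out[g] = Estimate(or_, lo, hi)
    return OddsRatioSet(estimates=out, reference=ref, provenance="crude")


def reorient_or(
    ors: OddsRatioSet,
    new_reference: str,
    table: GenotypeCountTable | None = None,
) -> OddsRatioSet:
    """Re-express an odds-ratio set against a different reference level.

    When the source count ``table`` is supplied, ORs and CIs are recomputed
    exactly from the cells.  Otherwise the point estimates are divided by
    the new reference's OR and the CI bounds scaled by the same factor — an
    approximation that ignores sampling error in the reference OR, noted in
    the provenance string.
    """
    if new_reference == ors.reference:
        return ors
    if new_reference not in ors.estimates:
        raise KeyError(f"level {new_reference!r} not present in the OR set")

    if table is not None:
        return crude_or(replace(table, reference=new_reference))

    pivot = ors.estimates[new_reference]
    out: dict[str, Estimate] = {}
    # Old reference becomes an explicit level: OR = 1/pivot, bounds swap.
    out[ors.reference] = Estimate(
        1 / pivot.point, 1 / pivot.upper, 1 / pivot.lower
    )
    for g, e in ors.estimates.items():
        if g == new_reference:
            continue
        out[g] = Estimate(e.point / pivot.point, e.lower / pivot.point, e.upper / pivot.point)
    return OddsRatioSet(
        estimates=out,
        reference=new_reference,
        provenance=f"{ors.provenance}; reoriented to {new_reference} (bound-ratio approx.)",
    )


# ---------------------------------------------------------------------------
# OR -> RR conversion
# ---------------------------------------------------------------------------

def or_to_rr(or_value: float, config: ConversionConfig | float = ConversionConfig()) -> float:
    """Convert an odds ratio to a risk ratio given the reference-group risk.

    RR = OR / (1 − p0 + p0·OR).  Equivalent to assigning the reference
    group risk p0, the exposed group odds (p0/(1−p0))·OR, and taking the
    ratio of the implied risks.  The conversion is exact under those
    definitions; RR always lies between 1 and OR.
    """
    if isinstance(config, (int, float)):
        config = ConversionConfig(p0=float(config))
    if not (or_value > 0):
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    return or_value / (1 - config.p0 + config.p0 * or_value)


def convert_or_set(
    ors: OddsRatioSet, config: ConversionConfig | float = ConversionConfig()
) -> RiskEstimateSet:
    """Apply the OR→RR conversion to points and both CI bounds alike."""
    if isinstance(config, (int, float)):
        config = ConversionConfig(p0=float(config))
    est = {
        g: Estimate(
            or_to_rr(e.point, config),
            or_to_rr(e.lower, config),
            or_to_rr(e.upper, config),
        )
        for g, e in ors.estimates.items()
    }
    return RiskEstimateSet(
        estimates=est,
        reference=ors.reference,
        provenance=f"converted-from-or(p0={config.p0:g}); {ors.provenance}",
    )


# ---------------------------------------------------------------------------
# Individual-level model fits
# ---------------------------------------------------------------------------

def _design_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str], reference: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if "outcome" not in cohort or "genotype" not in cohort:
        raise ValueError("cohort table needs 'genotype' and 'outcome' columns")
    y = cohort["outcome"].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    levels = [g for g in pd.unique(cohort["genotype"]) if g != reference]
    levels.sort()
    if reference not in set(cohort["genotype"]):
        raise ValueError(f"reference genotype {reference!r} absent from the cohort")
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for g in levels:
        cols.append((cohort["genotype"] == g).to_numpy(dtype=float))
        names.append(g)
    for c in covariates:
        cols.append(cohort[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), y, names


def _extract_set(
    res, names: list[str], genotype_levels: list[str], reference: str, provenance: str, cls
):
    params = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    est: dict[str, Estimate] = {}
    for g in genotype_levels:
        i = names.index(g)
        point = math.exp(params[i])
        lo, hi = _wald_ci(params[i], se[i])
        est[g] = Estimate(point, lo, hi)
    return cls(estimates=est, reference=reference, provenance=provenance)


def fit_log_binomial(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
    reference: str = REFERENCE_GENOTYPE,
    maxiter: int = 200,
) -> RiskEstimateSet:
    """Log-binomial GLM: exponentiated coefficients are risk ratios.

    Raises :class:`ConvergenceError` on non-convergence or when fitted
    probabilities escape (0, 1] — the classic failure mode when outcome
    probabilities in high-risk strata approach one.  The error message
    points at the logistic + OR→RR conversion fallback; the switch is left
    to the analyst.
    """
    X, y, names = _design_matrix(cohort, covariates, reference)
    if y.sum() == 0 or y.sum() == len(y):
        raise ConvergenceError(
            "outcome is constant; a log-binomial model cannot be fitted"
        )
    genotype_levels = [n for n in names if n not in ("intercept", *covariates)]
    # Start at the overall log-rate with zero effects: keeps early IRLS
    # iterations inside the valid mean space.
    start = np.zeros(X.shape[1])
    start[0] = math.log(max(y.mean(), 1e-12))
    with warnings.catch_warnings():
        # statsmodels warns that the log link can leave the binomial mean
        # space — that is the point of this model; violations are caught below
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log()))
    try:
        with np.errstate(all="ignore"):
            res = model.fit(start_params=start, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises assorted numeric errors
        raise ConvergenceError(
            f"log-binomial fit failed ({exc}); consider logistic regression "
            "followed by the OR→RR conversion at an assumed baseline risk"
        ) from exc
    mu = np.asarray(res.fittedvalues, dtype=float)
    # fitted probabilities at (or numerically on) the boundary make the Wald
    # covariance meaningless even when IRLS technically "converges"
    if not getattr(res, "converged", True) or not np.all((mu > 0) & (mu < 1 - 1e-8)) or not np.all(
        np.isfinite(np.asarray(res.bse, dtype=float))
    ):
        raise ConvergenceError(
            "log-binomial fit did not converge to a valid solution (fitted "
            "probabilities near or above 1); consider logistic regression "
            "followed by the OR→RR conversion at an assumed baseline risk"
        )
    return _extract_set(res, names, genotype_levels, reference, "log-binomial", RiskEstimateSet)


def fit_logistic(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
    reference: str = REFERENCE_GENOTYPE,
    maxiter: int = 200,
) -> OddsRatioSet:
    """Logistic GLM: exponentiated coefficients are odds ratios.

    With a genotype-only model this reproduces the crude contingency ORs
    exactly (saturated categorical predictor).
    """
    X, y, names = _design_matrix(cohort, covariates, reference)
    if y.sum() == 0 or y.sum() == len(y):
        raise ConvergenceError("outcome is constant; a logistic model cannot be fitted")
    genotype_levels = [n for n in names if n not in ("intercept", *covariates)]
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=maxiter)
    except Exception as exc:
        raise ConvergenceError(f"logistic fit failed ({exc})") from exc
    if not getattr(res, "converged", True) or not np.all(
        np.isfinite(np.asarray(res.bse, dtype=float))
    ):
        raise ConvergenceError(
            "logistic fit did not converge (possible complete separation)"
        )
    return _extract_set(res, names, genotype_levels, reference, "logistic", OddsRatioSet)
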