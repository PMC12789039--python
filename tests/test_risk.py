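"""Crude and model-based relative-risk estimation, OR re-orientation,
and the odds-to-risk conversion."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apoepaf import fixtures
from apoepaf.genotypes import GenotypeCountTable, tabulate_cohort
from apoepaf.risk import (
    ConversionConfig,
    ConvergenceError,
    Estimate,
    OddsRatioSet,
    convert_or_set,
    crude_or,
    crude_rr,
    fit_log_binomial,
    fit_logistic,
    or_to_rr,
    reorient_or,
)
from apoepaf.synthetic import CohortParams, generate_cohort


class TestCrudeRR:
    def test_a4_carrier_risk_ratio(self, a4_counts):
        # 1202/4390 positives among carriers vs 1/25 among ε2 homozygotes
        rrs = crude_rr(a4_counts)
        assert rrs["carrier"].point == pytest.approx((1202 / 4390) / (1 / 25), rel=1e-12)
        assert rrs["carrier"].point == pytest.approx(6.845, abs=5e-4)

    def test_equal_risks_give_unit_rr(self):
        t = GenotypeCountTable.from_cohort(
            {"e2/e2": 10, "x": 30}, {"e2/e2": 100, "x": 300}
        )
        assert crude_rr(t)["x"].point == pytest.approx(1.0)

    def test_doubling_counts_preserves_point_and_narrows_ci(self, a4_counts):
        doubled = GenotypeCountTable.from_cohort(
            {g: 2 * v for g, v in a4_counts.cases.items()},
            {g: 2 * v for g, v in a4_counts.totals.items()},
        )
        r1, r2 = crude_rr(a4_counts)["carrier"], crude_rr(doubled)["carrier"]
        assert r2.point == pytest.approx(r1.point, rel=1e-12)
        assert (r2.upper - r2.lower) < (r1.upper - r1.lower)

    def test_zero_reference_cases_error_and_correction(self):
        t = GenotypeCountTable.from_cohort(
            {"e2/e2": 0, "x": 30}, {"e2/e2": 100, "x": 300}
        )
        with pytest.raises(ZeroDivisionError, match="continuity"):
            crude_rr(t)
        assert crude_rr(t, correction=True)["x"].point > 0


class TestCrudeOR:
    def test_adgc_e4e4_odds_ratio(self, adgc_counts):
        ors = crude_or(adgc_counts)
        assert ors["e4/e4"].point == pytest.approx((623 / 10) / (5 / 19), rel=1e-12)
        assert ors["e4/e4"].point == pytest.approx(236.74, abs=0.005)

    def test_symmetric_table_gives_unit_or(self):
        t = GenotypeCountTable.from_case_control(
            {"e2/e2": 40, "x": 80}, {"e2/e2": 20, "x": 40}
        )
        assert crude_or(t)["x"].point == pytest.approx(1.0)

    def test_or_transitivity(self, adgc_counts):
        # OR(a vs c) = OR(a vs b) * OR(b vs c)
        vs_ref = crude_or(adgc_counts)
        vs_e33 = crude_or(dataclasses.replace(adgc_counts, reference="e3/e3"))
        assert vs_ref["e4/e4"].point == pytest.approx(
            vs_e33["e4/e4"].point * vs_ref["e3/e3"].point, rel=1e-12
        )

    def test_zero_cell_error_names_the_cell(self):
        t = GenotypeCountTable.from_case_control(
            {"e2/e2": 5, "x": 10}, {"e2/e2": 5, "x": 0}
        )
        with pytest.raises(ZeroDivisionError, match=r"controls\[x\]"):
            crude_or(t)
        assert crude_or(t, correction=True)["x"].point > 0


class TestReorient:
    def test_identity_when_reference_unchanged(self, adgc_counts):
        ors = crude_or(adgc_counts)
        assert reorient_or(ors, "e2/e2") is ors

    def test_count_based_reorientation_is_exact(self, adgc_counts):
        e33_table = dataclasses.replace(adgc_counts, reference="e3/e3")
        via_reorient = reorient_or(crude_or(e33_table), "e2/e2", table=e33_table)
        direct = crude_or(adgc_counts)
        for g in direct.levels:
            assert via_reorient[g].point == pytest.approx(direct[g].point, rel=1e-12)
            assert via_reorient[g].lower == pytest.approx(direct[g].lower, rel=1e-12)

    def test_summary_reorientation_points_and_involution(self, adgc_counts):
        ors = crude_or(adgc_counts)
        away = reorient_or(ors, "e3/e3")
        assert away["e4/e4"].point == pytest.approx(
            ors["e4/e4"].point / ors["e3/e3"].point, rel=1e-12
        )
        back = reorient_or(away, "e2/e2")
        for g in ors.levels:
            assert back[g].point == pytest.approx(ors[g].point, rel=1e-12)

    def test_missing_reference_errors(self, adgc_counts):
        with pytest.raises(KeyError):
            reorient_or(crude_or(adgc_counts), "nonexistent")


class TestOrToRr:
    def test_unit_or_maps_to_unit_rr(self):
        for p0 in (0.001, 0.01, 0.3, 0.9):
            assert or_to_rr(1.0, p0) == pytest.approx(1.0)

    def test_matches_two_group_construction(self):
        # reference risk p0; exposed odds = p0/(1-p0) * OR; RR by direct division
        or_, p0 = 236.74, 0.01
        odds = p0 / (1 - p0) * or_
        risk_exposed = odds / (1 + odds)
        assert or_to_rr(or_, p0) == pytest.approx(risk_exposed / p0, rel=1e-12)
        assert or_to_rr(236.74, 0.01) == pytest.approx(70.51, abs=5e-3)

    @given(
        or_=st.floats(0.05, 500.0),
        p0=st.floats(1e-6, 0.999, exclude_min=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bracketing_between_one_and_or(self, or_, p0):
        rr = or_to_rr(or_, p0)
        lo, hi = sorted((1.0, or_))
        assert lo - 1e-12 <= rr <= hi + 1e-12

    @given(or_=st.floats(1.001, 500.0))
    @settings(max_examples=100, derandomize=True)
    def test_limit_and_monotonicity_in_p0(self, or_):
        assert or_to_rr(or_, 1e-9) == pytest.approx(or_, rel=1e-6)
        grid = [or_to_rr(or_, p0) for p0 in (0.01, 0.05, 0.2, 0.5)]
        assert all(a > b for a, b in zip(grid, grid[1:]))

    def test_conversion_preserves_ci_ordering(self, adgc_counts):
        rrs = convert_or_set(crude_or(adgc_counts), ConversionConfig(p0=0.01))
        for g in rrs.levels:
            assert rrs[g].lower <= rrs[g].point <= rrs[g].upper

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            ConversionConfig(p0=0.0)
        with pytest.raises(ValueError):
            or_to_rr(-2.0, 0.01)


class TestModelFits:
    def test_log_binomial_recovers_generative_rr(self):
        params = CohortParams(
            n=200_000,
            baseline_risk=0.02,
            genotype_rr={
                "e2/e2": 1.0,
                "e2/e3": 1.5,
                "e3/e3": 2.0,
                "e2/e4": 4.0,
                "e3/e4": 6.0,
                "e4/e4": 10.0,
            },
            seed=11,
        )
        cohort = generate_cohort(params)
        res = fit_log_binomial(cohort)
        est = res["e4/e4"]
        se = (math.log(est.upper) - math.log(est.lower)) / (2 * 1.96)
        assert abs(math.log(est.point) - math.log(10.0)) < 3 * se

    def test_log_binomial_equals_crude_rr_when_saturated(self, medium_cohort):
        _, cohort = medium_cohort
        model = fit_log_binomial(cohort)
        crude = crude_rr(tabulate_cohort(cohort))
        for g in crude.levels:
            assert model[g].point == pytest.approx(crude[g].point, rel=1e-5)

    def test_constant_outcome_is_a_convergence_failure(self, medium_cohort):
        _, cohort = medium_cohort
        dead = cohort.assign(outcome=0)
        with pytest.raises(ConvergenceError):
            fit_log_binomial(dead)

    def test_nonconvergence_reports_instead_of_silent_estimate(self):
        # risks pinned at 1.0 in the top stratum push the log-link fit to
        # the boundary of the mean space
        params = CohortParams(
            n=4_000,
            baseline_risk=0.1,
            genotype_rr={
                "e2/e2": 1.0,
                "e2/e3": 2.0,
                "e3/e3": 3.0,
                "e2/e4": 5.0,
                "e3/e4": 8.0,
                "e4/e4": 10.0,
            },
            seed=3,
        )
        cohort = generate_cohort(params)
        # force the failure mode: every high-risk subject affected
        cohort.loc[cohort["genotype"] == "e4/e4", "outcome"] = 1
        with pytest.raises(ConvergenceError, match="logistic"):
            fit_log_binomial(cohort)

    def test_logistic_reproduces_crude_or(self):
        params = CohortParams(
            n=30_000,
            baseline_risk=0.03,
            genotype_rr={
                "e2/e2": 1.0,
                "e2/e3": 1.5,
                "e3/e3": 2.0,
                "e2/e4": 3.0,
                "e3/e4": 5.0,
                "e4/e4": 8.0,
            },
            sampling="case-control",
            n_cases=3_000,
            n_controls=3_000,
            seed=5,
        )
        cohort = generate_cohort(params)
        model = fit_logistic(cohort)
        table = tabulate_cohort(cohort)
        crude = crude_or(
            GenotypeCountTable.from_case_control(
                dict(table.cases),
                {g: table.totals[g] - table.cases[g] for g in table.levels},
            )
        )
        for g in crude.levels:
            assert model[g].point == pytest.approx(crude[g].point, rel=1e-5)

    def test_shuffled_outcome_gives_null_ors(self, medium_cohort):
        _, cohort = medium_cohort
        rng = np.random.default_rng(0)
        shuffled = cohort.assign(outcome=rng.permutation(cohort["outcome"].to_numpy()))
        model = fit_logistic(shuffled)
        for g in model.levels:
            assert model[g].lower < 1.0 < model[g].upper

    def test_rare_outcome_converted_rrs_approach_ors(self):
        params = CohortParams(
            n=400_000,
            baseline_risk=0.001,
            genotype_rr={
                "e2/e2": 1.0,
                "e2/e3": 1.5,
                "e3/e3": 2.0,
                "e2/e4": 4.0,
                "e3/e4": 6.0,
                "e4/e4": 10.0,
            },
            seed=13,
        )
        cohort = generate_cohort(params)
        ors = fit_logistic(cohort)
        rrs = convert_or_set(ors, ConversionConfig(p0=0.001))
        for g in ors.levels:
            assert rrs[g].point == pytest.approx(ors[g].point, rel=0.02)


class TestEstimateValidation:
    def test_ci_must_bracket_point(self):
        with pytest.raises(ValueError):
            Estimate(2.0, 2.5, 3.0)
        with pytest.raises(ValueError):
            Estimate(-1.0, -2.0, 0.0)

    def test_reference_not_among_estimates(self):
        with pytest.raises(ValueError):
            OddsRatioSet(estimates={"e2/e2": Estimate(1.0, 0.5, 2.0)})
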