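"""Baseline, allocation, counting fraction, and the year-by-year iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impact2cpr import (
    Allocation,
    ClientProfile,
    ServiceHistory,
    allocate_new_users,
    compute_baseline,
    counting_fraction,
    longacting_cohort,
    percentage_point_series,
    pre_existing_series,
    project_existing_users,
    run_trend,
    users_needed_to_maintain,
)

from conftest import make_random_case
from reference_impl import ref_trend


class TestBaseline:
    def test_contribution_is_users_over_denominator(self, simple_assumptions):
        history = ServiceHistory({(2004, "pill"): 65_000.0})  # 5,000 users
        baseline = compute_baseline(history, simple_assumptions, 2004)
        assert baseline.users == pytest.approx(5_000.0)
        assert baseline.cpr_contribution_points == pytest.approx(0.5)

    def test_empty_history_zero_baseline(self, simple_assumptions):
        baseline = compute_baseline(ServiceHistory({}), simple_assumptions, 2004)
        assert baseline.users == 0.0
        assert baseline.cpr_contribution == 0.0

    def test_missing_demography_year_errors(self, simple_assumptions):
        with pytest.raises(KeyError, match="1990"):
            compute_baseline(ServiceHistory({}), simple_assumptions, 1990)


class TestPreExisting:
    def test_no_lapm_before_trend_gives_zeros(self, simple_assumptions):
        history = ServiceHistory({(2006, "la5"): 100.0, (2004, "pill"): 130.0})
        series = pre_existing_series(history, simple_assumptions, range(2005, 2009), y0=2004)
        assert all(v == 0.0 for v in series.values())

    def test_single_baseline_cohort_is_shifted_trajectory(self, simple_assumptions, la5):
        history = ServiceHistory({(2004, "la5"): 100.0})
        series = pre_existing_series(history, simple_assumptions, range(2005, 2009), y0=2004)
        traj = longacting_cohort(100.0, la5)  # [90, 70, 50, 30, 10]
        assert series[2005] == pytest.approx(traj[1])
        assert series[2006] == pytest.approx(traj[2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_restricted_to_pre_baseline_cohorts(self, seed):
        from reference_impl import ref_cohort_users

        history, assumptions, _, y_start, y_end, exclude, ref = make_random_case(seed)
        series = pre_existing_series(
            history, assumptions, range(y_start, y_end + 1), y0=y_start - 1, exclude=exclude
        )
        for year, got in series.items():
            expected = ref_cohort_users(
                ref["services"], ref["methods"], year, ref["median_age"],
                ref["demography"], ref["life_levels"], set(exclude),
                max_provision_year=y_start - 1,
            )
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestUsersNeededToMaintain:
    def test_plain_subtraction(self):
        assert users_needed_to_maintain(1000, 400, 0) == 600

    def test_clamped_at_zero(self):
        assert users_needed_to_maintain(1000, 700, 400) == 0.0

    def test_zero_baseline_needs_nothing(self):
        assert users_needed_to_maintain(0, 0, 0) == 0.0


class TestAllocation:
    def test_situation_three_splits_adopters(self):
        alloc = allocate_new_users(600, 1000, (0.30, 0.50, 0.20))
        assert alloc.situation == 3
        assert alloc.maintain_users == pytest.approx(600)
        assert alloc.increase_users == pytest.approx(200)

    def test_situation_one_all_adopters_increase(self):
        alloc = allocate_new_users(600, 1000, (0.30, 0.65, 0.05))
        assert alloc.situation == 1
        assert alloc.maintain_users == pytest.approx(600)
        assert alloc.increase_users == pytest.approx(300)
        assert alloc.dropped_continuers == pytest.approx(50)

    def test_situation_two_everything_maintains(self):
        alloc = allocate_new_users(600, 500, (0.20, 0.40, 0.40))
        assert alloc.situation == 2
        assert alloc.maintain_users == pytest.approx(300)
        assert alloc.increase_users == 0.0

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            allocate_new_users(10, 10, (0.5, 0.2, 0.1))

    @given(
        needed=st.floats(min_value=0, max_value=1e6),
        new=st.one_of(st.just(0.0), st.floats(min_value=1e-3, max_value=1e6)),
        a=st.floats(min_value=0, max_value=1),
        c_frac=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, derandomize=True)
    def test_allocation_invariants(self, needed, new, a, c_frac):
        c = (1 - a) * c_frac
        alloc = allocate_new_users(needed, new, (a, c, 1 - a - c))
        assert alloc.maintain_users >= 0
        assert alloc.increase_users >= -1e-9
        # provider changers are never allocated
        assert alloc.maintain_users + alloc.increase_users <= new * (a + c) + 1e-6
        fraction = counting_fraction(alloc, new)
        assert 0.0 <= fraction <= min(1.0, a + c + 1e-9)


class TestCountingFraction:
    def test_from_allocation_examples(self):
        assert counting_fraction(Allocation(1, 600, 300), 1000) == pytest.approx(0.9)
        assert counting_fraction(Allocation(2, 300, 0), 500) == pytest.approx(0.6)

    def test_zero_new_users_defined_as_zero(self):
        assert counting_fraction(Allocation(2, 0, 0), 0) == 0.0


class TestProjectExistingUsers:
    def test_zero_fraction_projects_nothing(self, simple_assumptions):
        out = project_existing_users(
            {"la5": 0.0}, {"la5": 100.0}, 2005, simple_assumptions, range(2006, 2010)
        )
        assert all(v == 0.0 for v in out.values())

    def test_unit_fraction_reproduces_cohort_tail(self, simple_assumptions, la5):
        fy = 90.0  # first-year users of 100 services
        out = project_existing_users(
            {"la5": fy}, {"la5": 100.0}, 2005, simple_assumptions, range(2005, 2011)
        )
        traj = longacting_cohort(100.0, la5)
        assert out[2005] == 0.0  # no existing users in the provision year
        for n in range(1, 5):
            assert out[2005 + n] == pytest.approx(traj[n])

    def test_half_fraction_scales_trajectory(self, simple_assumptions):
        out = project_existing_users(
            {"la5": 45.0}, {"la5": 100.0}, 2005, simple_assumptions, range(2006, 2010)
        )
        assert [out[y] for y in range(2006, 2010)] == pytest.approx([35.0, 25.0, 15.0, 5.0])


class TestRunTrend:
    def test_all_provider_changers_counts_nothing_new(self, simple_assumptions):
        history = ServiceHistory(
            {(2004, "la5"): 100.0, (2005, "la5"): 100.0, (2006, "la5"): 100.0}
        )
        trend = run_trend(
            history, simple_assumptions, ClientProfile.constant(0, 0, 1), 2005, 2008
        )
        for yr in trend.years:
            assert yr.counting_fraction == 0.0
            assert yr.total_users_in_cpr == pytest.approx(yr.pre_existing + yr.existing)

    def test_steady_state_short_term_all_continuers(self, simple_assumptions):
        history = ServiceHistory({(y, "pill"): 1300.0 for y in range(2000, 2011)})
        trend = run_trend(
            history, simple_assumptions, ClientProfile.constant(0, 1, 0), 2005, 2010
        )
        for yr in trend.years:
            assert yr.total_users_in_cpr == pytest.approx(100.0)
            assert yr.pct_point_increase == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_identity(self):
        history, assumptions, profile, y_start, y_end, exclude, _ = make_random_case(21)
        trend = run_trend(history, assumptions, profile, y_start, y_end, exclude)
        for yr in trend.years:
            assert yr.total_users_in_cpr == pytest.approx(
                yr.pre_existing + yr.existing + yr.maintain + yr.increase, abs=1e-9
            )

    def test_counted_never_exceeds_modelled_users(self):
        from impact2cpr import estimate_users

        history, assumptions, profile, y_start, y_end, exclude, _ = make_random_case(22)
        trend = run_trend(history, assumptions, profile, y_start, y_end, exclude)
        modelled = estimate_users(history, assumptions, range(y_start, y_end + 1), exclude)
        for yr, yu in zip(trend.years, modelled.years):
            assert yr.total_users_in_cpr <= yu.total + 1e-9

    def test_zero_adopters_never_increase(self):
        history, assumptions, _, y_start, y_end, exclude, _ = make_random_case(23)
        trend = run_trend(
            history, assumptions, ClientProfile.constant(0.0, 0.6, 0.4), y_start, y_end, exclude
        )
        assert all(yr.increase == 0.0 for yr in trend.years)

    def test_zero_service_years_processed_as_degenerate(self, simple_assumptions):
        history = ServiceHistory({(2004, "la5"): 100.0})
        trend = run_trend(
            history, simple_assumptions, ClientProfile.constant(0.3, 0.5, 0.2), 2005, 2008
        )
        for yr in trend.years:
            assert yr.new_users == 0.0
            assert yr.maintain == 0.0 and yr.increase == 0.0

    def test_missing_profile_year_errors(self, simple_assumptions):
        history = ServiceHistory({(2005, "pill"): 130.0})
        profile = ClientProfile({2005: (0.3, 0.5, 0.2), 2006: (0.3, 0.5, 0.2)})
        with pytest.raises(KeyError, match="2007"):
            run_trend(history, simple_assumptions, profile, 2005, 2007)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_straight_line_reference(self, seed):
        history, assumptions, profile, y_start, y_end, exclude, ref = make_random_case(seed)
        trend = run_trend(history, assumptions, profile, y_start, y_end, exclude)
        expected = ref_trend(
            ref["services"], ref["methods"], ref["demography"], ref["life_levels"],
            ref["median_age"], ref["profile"], y_start, y_end, set(exclude),
            cpr_basis=ref["cpr_basis"],
        )
        assert trend.baseline.users == pytest.approx(expected["baseline_users"], rel=1e-9)
        assert trend.baseline.cpr_contribution == pytest.approx(
            expected["baseline_contribution"], rel=1e-9
        )
        for yr, exp in zip(trend.years, expected["years"]):
            for field in (
                "pre_existing", "existing", "maintain", "increase",
                "new_users", "counting_fraction", "total_users_in_cpr",
                "total_pct_contribution", "pct_point_increase",
            ):
                got = getattr(yr, field)
                want = exp[field if field != "total_pct_contribution" else "total_pct_contribution"]
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12), field


class TestPercentagePoints:
    def test_arithmetic(self, simple_assumptions):
        history = ServiceHistory({(2004, "pill"): 65_000.0, (2005, "pill"): 195_000.0})
        trend = run_trend(
            history, simple_assumptions, ClientProfile.constant(1, 0, 0), 2005, 2005
        )
        # 15,000 new users, all adopters: 5,000 maintain, 10,000 increase
        yr = trend.years[0]
        assert yr.total_users_in_cpr == pytest.approx(15_000)
        assert 100 * yr.total_pct_contribution == pytest.approx(1.5)
        assert 100 * yr.pct_point_increase == pytest.approx(1.0)

    def test_growing_denominator_shrinks_constant_contribution(self, la5):
        from impact2cpr import AssumptionSet, DemographicSeries, MethodSpec
        from conftest import flat_life_table

        demo = DemographicSeries.from_records(
            {y: (1e6 * 1.03 ** (y - 2000), 0.7, 60.0) for y in range(2000, 2015)}
        )
        assumptions = AssumptionSet(
            methods=[la5, MethodSpec(name="pill", category="short-term", units_per_year=13.0)],
            demography=demo,
            life_table=flat_life_table(),
            median_age_sterilisation=40.0,
        )
        history = ServiceHistory({(y, "pill"): 1300.0 for y in range(2000, 2012)})
        trend = run_trend(history, assumptions, ClientProfile.constant(0, 1, 0), 2005, 2010)
        increases = [yr.pct_point_increase for yr in trend.years]
        assert all(b < a for a, b in zip(increases, increases[1:]))
        frame = percentage_point_series(trend, assumptions)
        assert (frame["pct_point_increase"] < 0).all()  # constant users, growing WRA
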