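"""Cohort model: sojourn calibration, conservation, costs, aggregation."""

import dataclasses

import numpy as np
import pytest

from swiburden import (
    GlobalParams,
    aggregate_europe,
    calibrate_sojourns,
    compute_burden,
    run_cohort,
    simulate_patients,
)
from swiburden.country_data import CountryDataError
from swiburden.incidence import HillCurveParams, to_hazard_schedule
from swiburden.pathway import (
    HOSPITAL_PHASES,
    N_BASE,
    build_transition_model,
    stage_probs,
)
from swiburden.reporting import burden_results_frame


def with_values(record, **overrides):
    return dataclasses.replace(record, **overrides)


class TestSojournCalibration:
    @pytest.mark.parametrize("los", [5.0, 9.77, 14.4, 30.0])
    def test_mean_los_recovered(self, los, default_globals):
        plan = calibrate_sojourns(los, default_globals)
        assert plan.expected_los() == pytest.approx(los, rel=0.01)

    def test_one_day_stage_exits_certainly(self):
        assert stage_probs(1.0) == (1.0, 1.0)

    @pytest.mark.parametrize("los", [5.0, 9.77, 14.4, 30.0])
    def test_fundamental_matrix_oracle(self, los, complete_record,
                                       default_globals):
        """Expected hospital days from the absorbing-chain closed form
        (I - Q)^-1 row sums equal the target LOS."""
        gp = default_globals.replace(daily_mortality=0.0)
        plan = calibrate_sojourns(los, gp)
        params = HillCurveParams(i_max=0.0, t50=12.0, n_hill=2.0)
        sched = to_hazard_schedule(params, 365, 0.5)
        model = build_transition_model(
            with_values(complete_record, mean_los_days=los), gp, plan, sched
        )
        hosp = [N_BASE + p for p in HOSPITAL_PHASES]
        Q = model.M0[np.ix_(hosp, hosp)]
        t = np.linalg.solve(np.eye(len(hosp)) - Q, np.ones(len(hosp)))
        assert t[0] == pytest.approx(los, rel=1e-9)

    def test_icu_fraction_must_leave_room(self, default_globals):
        with pytest.raises(Exception):
            default_globals.replace(icu_fraction_of_los=1.2)

    def test_short_stay_rejected(self, default_globals):
        with pytest.raises(CountryDataError):
            calibrate_sojourns(0.5, default_globals)


class TestTransitionMatrices:
    def test_rows_stochastic_for_any_hazard(self, complete_record,
                                            default_globals):
        plan = calibrate_sojourns(
            complete_record.mean_los_days, default_globals
        )
        params = HillCurveParams(i_max=0.3, t50=12.0, n_hill=2.0)
        sched = to_hazard_schedule(
            params, 365, complete_record.sswi_share
        )
        model = build_transition_model(
            complete_record, default_globals, plan, sched
        )
        for day in (1, 30, 365):
            M = model.matrix(day)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((M >= -1e-15) & (M <= 1.0 + 1e-15))


class TestCohortRun:
    def test_conservation_and_monotone_accruals(self, complete_record,
                                                default_globals):
        trace = run_cohort(complete_record, default_globals)
        total = trace.occupancy.sum(axis=1)
        assert np.abs(total - 1.0).max() < 1e-9
        pub = trace.public_occupancy()
        assert np.abs(pub.sum(axis=1) - 1.0).max() < 1e-9
        for name in ("swi_icu_days", "swi_gw_days", "baseline_icu_days",
                     "baseline_gw_days", "readmission_fees", "readmissions",
                     "swi_events"):
            arr = getattr(trace, name)
            assert np.all(np.diff(arr) >= -1e-15)

    def test_zero_incidence_is_infection_free(self, complete_record,
                                              default_globals):
        rec = with_values(complete_record, swi_incidence=0.0)
        trace = run_cohort(rec, default_globals)
        burden = compute_burden(trace, rec)
        assert burden.total_swi_cost == 0.0
        assert burden.n_readmissions == 0.0
        assert burden.relative_increase == 0.0
        assert not burden.cost_per_swi_defined
        np.testing.assert_allclose(
            trace.occupancy, trace.baseline_occupancy, atol=1e-15
        )

    def test_all_mass_discharged_without_death(self, complete_record,
                                               default_globals):
        gp = default_globals.replace(daily_mortality=0.0)
        trace = run_cohort(complete_record, gp)
        final = trace.occupancy[-1]
        out_mass = final[N_BASE + 5] + final[11]  # naive + post out-of-hospital
        assert out_mass == pytest.approx(1.0, abs=1e-4)

    def test_baseline_decomposition_exact(self, complete_record,
                                          default_globals):
        """The infection-free component of a full run equals a run with the
        incidence set to zero."""
        full = run_cohort(complete_record, default_globals)
        null = run_cohort(
            with_values(complete_record, swi_incidence=0.0), default_globals
        )
        assert full.total_baseline_icu_days == pytest.approx(
            null.total_baseline_icu_days, abs=1e-12
        )
        assert full.total_baseline_gw_days == pytest.approx(
            null.total_baseline_gw_days, abs=1e-12
        )
        full_burden = compute_burden(full, complete_record)
        null_burden = compute_burden(
            null, with_values(complete_record, swi_incidence=0.0)
        )
        assert full_burden.baseline_cost == pytest.approx(
            null_burden.baseline_cost, rel=1e-12
        )

    def test_swi_cost_monotone_in_inputs(self, complete_record,
                                         default_globals):
        """Finite-difference sweeps: the SWI-attributable cost never
        decreases in incidence, unit costs, or extra stays."""
        sweeps = {
            "swi_incidence": [0.0, 0.02, 0.05, 0.10],
            "icu_day_cost": [500.0, 1500.0, 3000.0],
            "gw_day_cost": [200.0, 600.0, 1200.0],
            "sswi_extra_los_days": [0.0, 4.0, 10.0],
            "dswi_extra_los_days": [10.0, 25.0, 40.0],
        }
        for name, values in sweeps.items():
            costs = []
            for v in values:
                rec = with_values(complete_record, **{name: v})
                costs.append(
                    compute_burden(run_cohort(rec, default_globals), rec)
                    .total_swi_cost
                )
            assert np.all(np.diff(costs) >= -1e-9), name

    def test_incomplete_record_rejected(self, complete_record,
                                        default_globals):
        rec = with_values(complete_record, icu_day_cost=None, provenance={})
        with pytest.raises(CountryDataError, match="not fully imputed"):
            run_cohort(rec, default_globals)

    def test_short_hazard_schedule_rejected(self, complete_record,
                                            default_globals):
        params = HillCurveParams(i_max=0.05, t50=12.0, n_hill=2.0)
        short = to_hazard_schedule(params, 100, complete_record.sswi_share)
        with pytest.raises(ValueError, match="schedule covers"):
            run_cohort(complete_record, default_globals,
                       hazard_schedule=short)


class TestBurden:
    def test_procedure_volume_arithmetic(self, complete_record,
                                         default_globals):
        burden = compute_burden(
            run_cohort(complete_record, default_globals), complete_record
        )
        assert burden.n_cabg == pytest.approx(6000.0)  # 10M * 60 / 100k

    def test_relative_increase_is_cost_ratio(self, complete_record,
                                             default_globals):
        burden = compute_burden(
            run_cohort(complete_record, default_globals), complete_record
        )
        assert burden.relative_increase == pytest.approx(
            burden.total_swi_cost / burden.baseline_cost, rel=1e-9
        )

    def test_deep_infection_ward_cost_per_case(self, complete_record):
        """With all extra days in the general ward, no mortality and no
        readmission fee, each deep SWI costs extra-LOS x ward rate
        (37 x 1,010 = 37,370)."""
        gp = GlobalParams(
            daily_mortality=0.0,
            readmission_cost=0.0,
            dswi_extra_icu_fraction=0.0,
        )
        rec = with_values(
            complete_record,
            sswi_share=0.0,  # deep infections only
            gw_day_cost=1010.0,
            dswi_extra_los_days=37.0,
        )
        trace = run_cohort(rec, gp)
        per_case = (
            trace.total_swi_icu_days * rec.icu_day_cost
            + trace.total_swi_gw_days * rec.gw_day_cost
        ) / trace.total_swi_events
        assert per_case == pytest.approx(37 * 1010.0, rel=1e-2)

    def test_aggregate_totals_and_medians(self, complete_record,
                                          default_globals):
        burden = compute_burden(
            run_cohort(complete_record, default_globals), complete_record
        )
        single = aggregate_europe([burden])
        assert single.total_swi_cost == pytest.approx(burden.total_swi_cost)
        assert single.swi_incidence_median == pytest.approx(
            burden.swi_incidence
        )
        both = aggregate_europe([burden, dataclasses.replace(
            burden, country_id="COPY")])
        assert both.total_swi_cost == pytest.approx(2 * burden.total_swi_cost)
        assert both.swi_incidence_median == pytest.approx(burden.swi_incidence)

    def test_aggregate_matches_column_sum_oracle(self, synth_complete,
                                                 default_globals):
        results = [
            compute_burden(run_cohort(rec, default_globals), rec)
            for rec in synth_complete
        ]
        summary = aggregate_europe(results)
        frame = burden_results_frame(results)
        for col in ("total_swi_cost", "extra_icu_days", "extra_gw_days",
                    "n_readmissions"):
            assert getattr(summary, col) == pytest.approx(frame[col].sum())
        assert summary.swi_incidence_median == pytest.approx(
            frame["swi_incidence"].median()
        )


class TestMicrosimOracleQuick:
    def test_cohort_matches_patient_simulation(self, complete_record,
                                               default_globals):
        """Cohort expectations agree with a 60k-patient simulation within
        Monte-Carlo error (4 SE at unit-test scale)."""
        trace = run_cohort(complete_record, default_globals)
        ms = simulate_patients(
            complete_record, default_globals, 60_000,
            np.random.default_rng(2024),
        )
        rec = complete_record
        expected = {
            "swi_cost": (
                trace.total_swi_icu_days * rec.icu_day_cost
                + trace.total_swi_gw_days * rec.gw_day_cost
                + trace.total_readmission_fees
            ),
            "swi_icu_days": trace.total_swi_icu_days,
            "swi_gw_days": trace.total_swi_gw_days,
            "readmitted": trace.total_readmissions,
            "swi": trace.total_swi_events,
        }
        for name, value in expected.items():
            mean, se = ms.mean_se(name)
            assert abs(mean - value) <= 4 * se, (name, mean, value, se)
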