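"""Rate conversions, transition matrices, and the cohort trace."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from pcsk9cua import (HealthState as S, LifeTable, adjust_baseline_rate,
                      build_transition_matrix, make_test_parameters,
                      mortality_rates, prob_to_rate, rate_to_prob, run_cohort,
                      treated_rate)
from pcsk9cua.states import ABSORBING, ALIVE, TUNNEL_EXIT, TUNNELS


class TestRateConversions:
    @pytest.mark.parametrize("rate,t,expected", [
        (0.0, 1.0, 0.0),
        (0.009, 1.0, 1.0 - math.exp(-0.009)),
        (0.5, 2.0, 1.0 - math.exp(-1.0)),
    ])
    def test_exponential_formula(self, rate, t, expected):
        assert rate_to_prob(rate, t) == pytest.approx(expected, abs=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.1, 1.0)

    @given(r=st.floats(min_value=0.0, max_value=10.0))
    @hsettings(derandomize=True, max_examples=50)
    def test_inverse_round_trip_and_bounds(self, r):
        p = rate_to_prob(r, 1.0)
        assert 0.0 <= p < 1.0
        assert prob_to_rate(p, 1.0) == pytest.approx(r, abs=1e-9)


class TestBaselineAdjustment:
    def test_identity_at_zero_deltas(self):
        assert adjust_baseline_rate(0.007, 1.2, 0.0, 0.78, 0.0) == 0.007

    @pytest.mark.parametrize("r0,hr,da,rr,dldl,expected", [
        (0.012, 1.0, 0.0, 0.78, 1.0, 0.00936),     # LDL-C calibration only
        (0.009, 1.05, 2.0, 0.78, 0.0, 0.0099225),  # age calibration only
    ])
    def test_multiplicative_calibration(self, r0, hr, da, rr, dldl, expected):
        assert adjust_baseline_rate(r0, hr, da, rr, dldl) == pytest.approx(
            expected, abs=1e-12)

    def test_nonpositive_ratios_rejected(self):
        with pytest.raises(ValueError):
            adjust_baseline_rate(0.01, 0.0, 1.0, 0.78, 1.0)
        with pytest.raises(ValueError):
            adjust_baseline_rate(0.01, 1.0, 1.0, -0.5, 1.0)


class TestTreatedRate:
    def test_comparator_arm_unchanged(self):
        assert treated_rate(0.009, 0.74, 0.0) == 0.009

    @pytest.mark.parametrize("r0,rr,dldl,expected", [
        (0.009, 0.74, 1.79, 0.009 * 0.74 ** 1.79),
        (0.004, 0.80, 1.36, 0.004 * 0.80 ** 1.36),
    ])
    def test_proportional_risk_reduction(self, r0, rr, dldl, expected):
        assert treated_rate(r0, rr, dldl) == pytest.approx(expected, abs=1e-12)

    def test_rr_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            treated_rate(0.009, 1.2, 1.0)
        with pytest.raises(ValueError):
            treated_rate(0.009, 0.0, 1.0)


class TestMortality:
    def _flat_table(self, all_cause=0.020, cv=0.010):
        ages = np.arange(40, 101)
        return LifeTable(ages, np.full(61, all_cause), np.full(61, cv))

    def test_untreated_rates_match_table(self, base_params):
        cv, non_cv = mortality_rates(self._flat_table(), 60.0, 0.0,
                                     base_params.effects, False,
                                     base_params.multipliers)
        assert cv == pytest.approx(0.010)
        assert non_cv == pytest.approx(0.010)

    def test_treated_post_event_scaling(self, base_params):
        cv, non_cv = mortality_rates(self._flat_table(), 60.0, 1.0,
                                     base_params.effects, True,
                                     base_params.multipliers)
        assert cv == pytest.approx(0.010 * 0.86 * 1.31, abs=1e-12)
        assert non_cv == pytest.approx(0.010)  # never treatment-affected

    def test_age_below_table_rejected(self, base_params):
        with pytest.raises(ValueError):
            mortality_rates(self._flat_table(), 20.0, 0.0,
                            base_params.effects, False,
                            base_params.multipliers)

    def test_cv_above_all_cause_rejected(self):
        with pytest.raises(ValueError, match="cv_rate"):
            self._flat_table(all_cause=0.01, cv=0.02)


class TestTransitionMatrix:
    def test_absorbing_rows_are_unit_vectors(self, base_params):
        M = build_transition_matrix(base_params, base_params.comparator, 0)
        for s in ABSORBING:
            expected = np.zeros(11)
            expected[s] = 1.0
            assert np.array_equal(M.probs[s], expected)

    def test_tunnel_exits_when_nothing_competes(self, degenerate_params):
        # no events and a zero-mortality table: tunnels drain with certainty
        lt = degenerate_params.life_table
        quiet = dataclasses.replace(
            degenerate_params,
            life_table=LifeTable(lt.ages, np.zeros(len(lt.ages)),
                                 np.zeros(len(lt.ages))))
        M = build_transition_matrix(quiet, quiet.comparator, 0)
        for tunnel, exit_state in TUNNEL_EXIT.items():
            assert M.probs[tunnel, exit_state] == pytest.approx(1.0)

    def test_rows_stochastic_for_every_regimen(self, base_params):
        for regimen in base_params.regimens:
            for cycle in (0, 15, 29):
                M = build_transition_matrix(base_params, regimen, cycle)
                assert np.all(M.probs >= 0)
                np.testing.assert_allclose(M.probs.sum(axis=1), 1.0,
                                           atol=1e-12)

    def test_competing_risks_shrink_marginal_probability(self, base_params):
        # joint exit apportionment is strictly below the single-cause
        # conversion whenever other causes compete
        M = build_transition_matrix(base_params, base_params.comparator, 0)
        assert M.probs[S.NO_CVD, S.MI_Y1] < rate_to_prob(0.009, 1.0)

    def test_structural_zeros(self, base_params):
        M = build_transition_matrix(base_params, base_params.comparator, 0)
        assert M.probs[S.POST_IS, S.MI2_Y1] == 0.0  # first MI, not a recurrence
        assert M.probs[S.POST_MI, S.IS2_Y1] == 0.0
        assert M.probs[S.CV_DEATH, S.NO_CVD] == 0.0
        # tunnels cannot linger: a first-year state never maps to itself
        # except via a same-type recurrent event (MI2/IS2 re-entry)
        assert M.probs[S.MI_Y1, S.MI_Y1] == 0.0
        assert M.probs[S.IS_Y1, S.IS_Y1] == 0.0

    def test_cycle_outside_horizon_rejected(self, base_params):
        with pytest.raises(ValueError):
            build_transition_matrix(base_params, base_params.comparator, 30)


class TestCohortTrace:
    def test_nothing_happens_without_rates(self, degenerate_params):
        lt = degenerate_params.life_table
        quiet = dataclasses.replace(
            degenerate_params,
            life_table=LifeTable(lt.ages, np.zeros(len(lt.ages)),
                                 np.zeros(len(lt.ages))))
        trace = run_cohort(quiet, quiet.comparator)
        assert np.all(trace.occupancy[:, S.NO_CVD] == 1.0)
        assert np.all(trace.revasc_events == 0.0)

    def test_trace_invariants_base_case(self, base_params):
        for regimen in base_params.regimens[:3]:
            trace = run_cohort(base_params, regimen)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                       atol=1e-10)
            assert trace.occupancy[0, S.NO_CVD] == 1.0
            dead = trace.occupancy[:, [S.CV_DEATH, S.NON_CV_DEATH]].sum(axis=1)
            assert np.all(np.diff(dead) >= -1e-12)

    def test_ldl_reduction_never_increases_harm(self, base_params):
        """Cumulative MI, IS and CV-death occupancy are monotone
        non-increasing in the LDL-C reduction, cycle by cycle."""
        def harm(dldl):
            p = base_params.replace_value(
                "ldl_reduction.Evolocumab 140 mg Q2W", dldl)
            occ = run_cohort(p, p.regimen("Evolocumab 140 mg Q2W")).occupancy
            mi = occ[:, [S.MI_Y1, S.POST_MI, S.MI2_Y1, S.POST_MI2]].sum(axis=1)
            is_ = occ[:, [S.IS_Y1, S.POST_IS, S.IS2_Y1, S.POST_IS2]].sum(axis=1)
            return mi, is_, occ[:, S.CV_DEATH]

        for lo, hi in [(0.0, 0.5), (0.5, 1.79), (1.79, 2.5)]:
            for weak, strong in zip(harm(lo), harm(hi)):
                assert np.all(strong <= weak + 1e-14)

    def test_trace_matches_explicit_hand_iteration(self, simple_params):
        """Brute-force oracle: rebuild each cycle's transition row-by-row
        with scalar arithmetic and iterate the occupancy vector by hand."""
        params = simple_params
        regimen = params.regimen("Drug A Q2W")
        eff, mult, rates = params.effects, params.multipliers, params.baseline_rates
        d = regimen.ldl_reduction_mean
        r_mi = rates.nonfatal_mi * eff.rr_mi ** d
        r_is = rates.nonfatal_stroke * eff.rr_stroke ** d

        mi_mult = {S.NO_CVD: 1, S.POST_IS: 1, S.POST_IS2: 1,
                   S.POST_MI: mult.recurrent_mi, S.POST_MI2: mult.mi_2plus,
                   S.MI_Y1: mult.recurrent_mi * mult.any_cv_event_past_year,
                   S.MI2_Y1: mult.mi_2plus * mult.any_cv_event_past_year,
                   S.IS_Y1: mult.any_cv_event_past_year,
                   S.IS2_Y1: mult.any_cv_event_past_year}
        is_mult = {S.NO_CVD: 1, S.POST_MI: 1, S.POST_MI2: 1,
                   S.POST_IS: mult.recurrent_stroke,
                   S.POST_IS2: mult.stroke_2plus,
                   S.IS_Y1: mult.recurrent_stroke * mult.any_cv_event_past_year,
                   S.IS2_Y1: mult.stroke_2plus * mult.any_cv_event_past_year,
                   S.MI_Y1: mult.any_cv_event_past_year,
                   S.MI2_Y1: mult.any_cv_event_past_year}
        mi_path = {S.MI_Y1, S.POST_MI, S.MI2_Y1, S.POST_MI2}
        is_path = {S.IS_Y1, S.POST_IS, S.IS2_Y1, S.POST_IS2}

        occ = {s: 0.0 for s in S}
        occ[S.NO_CVD] = 1.0
        hand = [dict(occ)]
        for k in range(3):
            age = params.settings.start_age + k
            cv0 = params.life_table.cv(age) * eff.rr_vascular_death ** d
            non_cv = params.life_table.all_cause(age) - params.life_table.cv(age)
            nxt = {s: 0.0 for s in S}
            nxt[S.CV_DEATH] = occ[S.CV_DEATH]
            nxt[S.NON_CV_DEATH] = occ[S.NON_CV_DEATH]
            for s in ALIVE:
                cv = cv0 * (mult.cv_death_post_event if s in TUNNELS else 1.0)
                mi = r_mi * mi_mult[s]
                is_ = r_is * is_mult[s]
                total = mi + is_ + cv + non_cv
                exit_p = 1.0 - math.exp(-total)
                stay = TUNNEL_EXIT.get(s, s)
                share = exit_p / total if total > 0 else 0.0
                nxt[S.MI2_Y1 if s in mi_path else S.MI_Y1] += occ[s] * mi * share
                nxt[S.IS2_Y1 if s in is_path else S.IS_Y1] += occ[s] * is_ * share
                nxt[S.CV_DEATH] += occ[s] * cv * share
                nxt[S.NON_CV_DEATH] += occ[s] * non_cv * share
                nxt[stay] += occ[s] * (1.0 - exit_p)
            occ = nxt
            hand.append(dict(occ))

        trace = run_cohort(params, regimen)
        for k, row in enumerate(hand):
            for s in S:
                assert trace.occupancy[k, s] == pytest.approx(row[s],
                                                              abs=1e-12)
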