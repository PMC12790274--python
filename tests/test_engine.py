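"""Microsimulation engine: treatment logic, event probabilities, cycle accounting,
common-random-number pairing, and agreement with the deterministic recursion."""

import dataclasses

import numpy as np
import pytest

import osteoscreen as osc
from osteoscreen.engine import (
    IndividualState,
    annual_death_prob,
    annual_fracture_prob,
    draw_streams,
    run_cohort,
    simulate_individual,
    simulate_year,
    treatment_rr,
    update_persistence,
)
from osteoscreen.oracle import cohort_expected_value
from osteoscreen.params import FractureSite, LifeTable, Sex
from osteoscreen.uncertainty import ScenarioSpec, apply_scenario

from conftest import history_independent


class _FixedU:
    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


def _state(**kw) -> IndividualState:
    defaults = dict(age=70, sex=Sex.FEMALE, osteoporotic=False)
    defaults.update(kw)
    return IndividualState(**defaults)


class TestTreatmentRR:
    def test_on_treatment_full_effect(self, base_params):
        s = _state(on_treatment=True, drug="denosumab")
        assert treatment_rr(s, FractureSite.HIP, base_params.drugs["denosumab"]) == 0.60

    def test_denosumab_effect_gone_one_year_after_stop(self, base_params):
        s = _state(on_treatment=False, drug="denosumab", years_on_treatment=3,
                   years_since_stop=1.0)
        assert treatment_rr(s, FractureSite.HIP, base_params.drugs["denosumab"]) == 1.0

    def test_alendronate_linear_waning_over_duration(self, base_params):
        s = _state(on_treatment=False, drug="alendronate", years_on_treatment=3,
                   years_since_stop=1.5)
        rr = treatment_rr(s, FractureSite.HIP, base_params.drugs["alendronate"])
        assert rr == pytest.approx(1 - 0.33 * (1 - 1.5 / 3))  # 0.835

    def test_no_rebound_above_baseline(self, base_params):
        s = _state(on_treatment=False, drug="alendronate", years_on_treatment=2,
                   years_since_stop=50.0)
        assert treatment_rr(s, FractureSite.VERTEBRAL,
                            base_params.drugs["alendronate"]) == 1.0

    def test_requires_assigned_drug(self, base_params):
        with pytest.raises(ValueError):
            treatment_rr(_state(), FractureSite.HIP, base_params.drugs["alendronate"])


class TestPersistence:
    def test_conditional_discontinuation_hazards(self, base_params):
        d = base_params.drugs["alendronate"]
        assert d.discontinuation_hazard(1) == pytest.approx(1 - 0.732)
        assert d.discontinuation_hazard(2) == pytest.approx(1 - 0.336 / 0.732)
        for year in (3, 4, 5):
            assert d.discontinuation_hazard(year) == 0.0

    def test_stop_and_stay_decisions(self, base_params):
        d, mix = base_params.drugs["alendronate"], base_params.mix
        s = _state(on_treatment=True, drug="alendronate", years_on_treatment=0)
        update_persistence(s, d, mix, _FixedU(0.5))  # 0.5 > 0.268: stays on
        assert s.on_treatment and s.years_on_treatment == 1
        update_persistence(s, d, mix, _FixedU(0.1))  # 0.1 < 0.541: stops at year 2
        assert not s.on_treatment and s.years_since_stop == 0.0

    def test_forced_stop_at_max_duration(self, base_params):
        d, mix = base_params.drugs["alendronate"], base_params.mix
        s = _state(on_treatment=True, drug="alendronate", years_on_treatment=4)
        update_persistence(s, d, mix, _FixedU(0.999))
        assert not s.on_treatment and s.years_on_treatment == 5

    def test_stopped_clock_advances(self, base_params):
        d, mix = base_params.drugs["denosumab"], base_params.mix
        s = _state(on_treatment=False, drug="denosumab", years_on_treatment=2,
                   years_since_stop=0.0)
        update_persistence(s, d, mix, _FixedU(0.9))
        assert s.years_since_stop == 1.0


class TestAnnualFractureProb:
    def test_baseline_rate_conversion(self, base_params):
        s = _state(age=75)
        p = annual_fracture_prob(s, FractureSite.HIP, base_params)
        assert p == pytest.approx(1 - np.exp(-0.0030), abs=1e-7)  # 0.0029955

    def test_tscore_multiplier_applies_to_osteoporotic(self, base_params):
        s = _state(age=75, osteoporotic=True)
        p = annual_fracture_prob(s, FractureSite.HIP, base_params)
        assert p == pytest.approx(1 - np.exp(-0.0030 * 2.250), abs=1e-7)

    def test_fracture_history_raises_risk(self, base_params):
        s = _state(age=75, prior_fractures=np.array([0, 1, 0]),
                   years_since_last_fracture=1.0)
        p = annual_fracture_prob(s, FractureSite.HIP, base_params)
        assert p == pytest.approx(1 - np.exp(-0.0030 * 2.0), abs=1e-7)

    def test_identity_when_no_multipliers(self, base_params):
        s = _state(age=62, sex=Sex.MALE)
        p = annual_fracture_prob(s, FractureSite.VERTEBRAL, base_params)
        assert p == pytest.approx(1 - np.exp(-0.0025), abs=1e-9)


class TestAnnualDeathProb:
    def test_background_mortality_without_history(self, base_params):
        s = _state(age=80)
        assert annual_death_prob(s, base_params) == base_params.life_tables[Sex.FEMALE].q(80)

    def test_attribution_zero_silences_excess(self, base_params):
        pfm = base_params.post_fracture_mortality
        p = base_params.with_(post_fracture_mortality=dataclasses.replace(
            pfm, attribution=0.0))
        s = _state(age=80, events_this_cycle=np.array([True, False, False]),
                   years_since_last_hv=2.0)
        assert annual_death_prob(s, p) == p.life_tables[Sex.FEMALE].q(80)

    def test_first_year_hip_excess_formula(self, base_params):
        qx = np.full(56, 0.02)
        qx[-1] = 1.0
        lt = {sex: LifeTable(sex=sex, qx=qx) for sex in Sex}
        p = base_params.with_(life_tables=lt)
        s = _state(age=70, events_this_cycle=np.array([True, False, False]))
        # q = 0.02 + 0.25 * 0.10 with the packaged stand-in excess
        assert annual_death_prob(s, p) == pytest.approx(0.045)

    def test_nhnv_event_adds_nothing(self, base_params):
        s = _state(age=70, events_this_cycle=np.array([False, False, True]))
        assert annual_death_prob(s, base_params) == base_params.life_tables[Sex.FEMALE].q(70)


def _zero_incidence(params):
    inc = params.incidence.__class__(values=np.zeros_like(params.incidence.values))
    return params.with_(incidence=inc)


class TestSimulateYear:
    def test_event_free_cycle_accrues_baseline_utility(self, base_params):
        p = _zero_incidence(base_params)
        s = _state(age=70)
        rng = _FixedU(0.999)  # no fracture, no death
        cost, qaly, ly = simulate_year(s, p, rng)
        assert cost == 0.0
        assert ly == 1.0
        assert qaly == pytest.approx(0.850 * 1.045 ** -0.5)

    def test_most_severe_fracture_caps_utility_loss(self, base_params):
        # force hip + vertebral events in the same cycle
        inc = base_params.incidence.values.copy()
        inc[:, 0, :] = 1e3
        inc[:, 1, :] = 1e3
        p = base_params.with_(incidence=base_params.incidence.__class__(values=inc))
        s = _state(age=70)
        cost, qaly, ly = simulate_year(s, p, _FixedU(0.3))
        assert s.prior_fractures[0] == 1 and s.prior_fractures[1] == 1
        credit = ly  # 0.5 if the excess mortality draw killed, else 1.0
        assert qaly == pytest.approx(0.850 * 0.55 * credit * 1.045 ** -0.5)

    def test_subsequent_year_multiplier_keyed_to_worst_site(self, base_params):
        p = _zero_incidence(base_params)
        s = _state(age=71, most_severe_hist=int(FractureSite.VERTEBRAL),
                   prior_fractures=np.array([0, 1, 0]), years_since_last_fracture=1.0,
                   years_since_last_hv=1.0, cycle=1)
        _, qaly, _ = simulate_year(s, p, _FixedU(0.999))
        assert qaly == pytest.approx(0.838 * 0.85 * 1.045 ** -1.5)

    def test_dead_individuals_cannot_cycle(self, base_params):
        s = _state(alive=False)
        with pytest.raises(ValueError):
            simulate_year(s, base_params, _FixedU(0.5))


class TestNullModel:
    def test_no_fractures_no_treatment_means_no_cost(self, base_params):
        p = _zero_incidence(base_params)
        streams = draw_streams(1, seed=21)
        acc = simulate_individual((65, Sex.FEMALE, True), p, "no_screening",
                                  streams.person(0))
        assert acc.disc_cost == 0.0
        assert acc.fracture_count.sum() == 0
        assert acc.life_years > 0

    def test_survival_driven_by_life_table_alone(self, base_params):
        """With attribution 0, mean life-years equal the roster-mixed life expectancy."""
        p = base_params.with_(post_fracture_mortality=dataclasses.replace(
            base_params.post_fracture_mortality, attribution=0.0))
        roster = osc.make_population(40_000, p.population, seed=22)
        flags = osc.assign_osteoporosis(roster, p.prevalence, seed=22)
        res = run_cohort(roster, flags, p, seed=22)
        expected = np.mean([p.life_tables[Sex(s)].life_expectancy(int(a))
                            for s, a in zip(roster.sexes, roster.ages)])
        se = res.no_screening.se("life_years")
        assert abs(res.no_screening.mean_life_years - expected) < 3 * se


class TestPairing:
    def test_disabled_screening_makes_arms_bit_identical(self, base_params, small_cohort):
        roster, flags = small_cohort
        p = base_params.with_(
            test=dataclasses.replace(base_params.test, unit_cost=0.0),
            cascade=dataclasses.replace(base_params.cascade, p_dxa_uptake=0.0))
        res = run_cohort(roster, flags, p, seed=31)
        assert np.array_equal(res.screening.cost, res.no_screening.cost)
        assert np.array_equal(res.screening.qaly, res.no_screening.qaly)
        assert np.array_equal(res.screening.fractures, res.no_screening.fractures)

    def test_unflagged_individual_differs_only_by_ai_cost(self, base_params):
        streams = draw_streams(1, seed=33)
        streams.cascade[0, 0] = 0.999  # never flagged
        entry = (60, Sex.FEMALE, True)
        scr = simulate_individual(entry, base_params, "screening", streams.person(0))
        ns = simulate_individual(entry, base_params, "no_screening", streams.person(0))
        assert scr.disc_cost - ns.disc_cost == pytest.approx(base_params.test.unit_cost)
        assert scr.disc_qaly == ns.disc_qaly
        assert scr.life_years == ns.life_years

    def test_determinism_across_runs(self, base_params, small_cohort):
        roster, flags = small_cohort
        r1 = run_cohort(roster, flags, base_params, seed=41)
        r2 = run_cohort(roster, flags, base_params, seed=41)
        assert np.array_equal(r1.screening.cost, r2.screening.cost)
        assert np.array_equal(r1.no_screening.fractures, r2.no_screening.fractures)


def test_scalar_and_vector_paths_agree_exactly(base_params):
    """The per-person loop and the vectorised cohort consume the same streams
    and must produce identical trajectories."""
    roster = osc.make_population(150, base_params.population, seed=51)
    flags = osc.assign_osteoporosis(roster, base_params.prevalence, seed=51)
    streams = draw_streams(roster.n, seed=51)
    res = run_cohort(roster, flags, base_params, seed=51)
    for arm_name, arm in (("screening", res.screening),
                          ("no_screening", res.no_screening)):
        for i in range(roster.n):
            acc = simulate_individual((roster.ages[i], roster.sexes[i], flags[i]),
                                      base_params, arm_name, streams.person(i))
            assert acc.disc_cost == pytest.approx(arm.cost[i], rel=1e-12, abs=1e-7)
            assert acc.disc_qaly == pytest.approx(arm.qaly[i], rel=1e-12, abs=1e-10)
            assert acc.life_years == arm.life_years[i]
            assert np.array_equal(acc.fracture_count, arm.fractures[:, i])


def test_conservation_bounds_per_individual(base_params, small_cohort):
    roster, flags = small_cohort
    res = run_cohort(roster, flags, base_params, seed=61)
    for arm in (res.screening, res.no_screening):
        assert np.all(arm.qaly <= arm.life_years + 1e-9)
        assert np.all(arm.life_years <= 105 - roster.ages + 1e-9)
        assert np.all(arm.cost >= 0)


class TestMonotonicity:
    def test_higher_fracture_costs_raise_total_costs(self, base_params, small_cohort):
        roster, flags = small_cohort
        spec = ScenarioSpec("cost_up", "t", (("costs.fracture_first_year.*", "mul", 2.0),))
        res_lo = run_cohort(roster, flags, base_params, seed=71)
        res_hi = run_cohort(roster, flags, apply_scenario(base_params, spec), seed=71)
        assert res_hi.no_screening.mean_cost > res_lo.no_screening.mean_cost

    def test_stronger_drugs_raise_incremental_qalys(self, base_params):
        roster = osc.make_population(20_000, base_params.population, seed=72)
        flags = np.ones(roster.n, dtype=bool)
        spec = ScenarioSpec("eff_up", "t", (("drugs.*.rr.*", "scale_decrement", 1.8),))
        res_lo = run_cohort(roster, flags, base_params, seed=72)
        res_hi = run_cohort(roster, flags, apply_scenario(base_params, spec), seed=72)
        dq_lo = (res_lo.screening.qaly - res_lo.no_screening.qaly).mean()
        dq_hi = (res_hi.screening.qaly - res_hi.no_screening.qaly).mean()
        assert dq_hi > dq_lo

    def test_treatment_reduces_fractures_under_shared_uniforms(self, base_params):
        """Certain treatment for a diseased cohort: screening arm fractures fall."""
        p = base_params.with_(
            test=dataclasses.replace(base_params.test, sensitivity=1.0),
            cascade=dataclasses.replace(base_params.cascade, p_dxa_uptake=1.0,
                                        p_treat_init=1.0))
        roster = osc.make_population(5000, p.population, seed=73)
        flags = np.ones(roster.n, dtype=bool)
        res = run_cohort(roster, flags, p, seed=73)
        assert res.screening.mean_fractures < res.no_screening.mean_fractures


class TestOracleEquivalence:
    def test_recursion_requires_simplified_settings(self, base_params, small_cohort):
        roster, flags = small_cohort
        with pytest.raises(ValueError):
            cohort_expected_value(roster, flags, base_params, "no_screening")

    def test_degenerate_no_fractures_matches_life_table(self, base_params):
        p = _zero_incidence(history_independent(base_params))
        roster = osc.make_population(500, p.population, seed=81)
        flags = np.zeros(roster.n, dtype=bool)
        out = cohort_expected_value(roster, flags, p, "no_screening")
        expected_ly = np.mean([p.life_tables[Sex(s)].life_expectancy(int(a))
                               for s, a in zip(roster.sexes, roster.ages)])
        assert out["life_years"] == pytest.approx(expected_ly, rel=1e-9)
        assert out["fractures"] == 0.0 and out["cost"] == 0.0
        assert out["qaly"] < out["life_years"]

    def test_microsim_matches_recursion_within_3se(self, base_params):
        p = history_independent(base_params)
        roster = osc.make_population(40_000, p.population, seed=82)
        flags = osc.assign_osteoporosis(roster, p.prevalence, seed=82)
        res = run_cohort(roster, flags, p, seed=82)
        for arm_name, arm in (("screening", res.screening),
                              ("no_screening", res.no_screening)):
            exact = cohort_expected_value(roster, flags, p, arm_name)
            for key, mean in (("cost", arm.mean_cost), ("qaly", arm.mean_qaly),
                              ("life_years", arm.mean_life_years),
                              ("fractures", arm.mean_fractures)):
                se = max(arm.se("fractures" if key == "fractures" else key), 1e-12)
                assert abs(mean - exact[key]) < 3 * se, (arm_name, key)
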