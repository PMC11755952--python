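"""Base case, DSA, PSA, CEAC and scenario orchestration."""

import numpy as np
import pytest

from wwcea import (
    base_case,
    ceac,
    default_dsa_spec,
    one_way_dsa,
    psa_distributions,
    run_psa,
    run_scenarios,
    sample_psa_draw,
)
from wwcea.analyses import (
    DsaParameter,
    ScenarioSpec,
    evaluate_strategies,
    scenario_specs,
    with_override,
)
from wwcea.params import (
    IMMEDIATE_ED,
    WATCHFUL_WAITING,
    ParamDistribution,
    ParameterError,
)
from wwcea.rewards import accumulate, cycle_rewards
from wwcea.markov import accumulate_batch, run_cohort


class TestBaseCase:
    def test_strategy_equivalence_limit(self, life_table, short_params):
        p = short_params.copy()
        p.epi.p_no_eai = 1.0
        p.epi.p_biphasic = 0.0
        p.epi.ww_fatality_multiplier = 1.0
        # nobody carries a device, so no pre-ED autoinjector use either
        p.cost.p_eai_before_ed = 0.0
        p = p.refresh_derived()
        # route the full fatality target through hospital so both arms match
        from wwcea.params import calibrate_hospitalization_prob

        p.epi.p_hosp_given_ed = calibrate_hospitalization_prob(
            p.epi.p_severe_annual, p.epi.p_fatal_overall_annual, p.epi.p_fatal_hosp
        )
        cmp_ = base_case(p, life_table)
        assert cmp_.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert cmp_.delta_cost == pytest.approx(0.0, abs=1e-9)


class TestBatchEngine:
    def test_batch_path_equals_trace_path(self, life_table, short_params):
        """The fused batched propagate-and-accumulate reproduces the
        readable single-cohort path exactly."""
        from wwcea import synthetic_parameters

        params_list = []
        for seed in (1, 2, 3):
            p = synthetic_parameters(seed)
            p.settings.horizon_years = short_params.settings.horizon_years
            params_list.append(p)
        for strategy in (WATCHFUL_WAITING, IMMEDIATE_ED):
            specs = [cycle_rewards(strategy, "healthcare", p) for p in params_list]
            out = accumulate_batch(
                strategy,
                params_list,
                life_table,
                np.stack([s.cycle_cost_vector for s in specs]),
                np.stack([s.cycle_utility_vector for s in specs]),
            )
            for i, p in enumerate(params_list):
                trace = run_cohort(strategy, p, life_table)
                res = accumulate(trace, specs[i], p.settings)
                assert out["cost"][i] == pytest.approx(res.total_cost_discounted, rel=1e-12)
                assert out["qaly"][i] == pytest.approx(res.total_qaly_discounted, rel=1e-12)
                assert out["fa_death_risk"][i] == pytest.approx(res.fa_death_risk, rel=1e-12)


class TestDsa:
    def test_zero_effect_parameter_has_flat_icer(self, life_table, short_params):
        """Remission utility cannot move the ICER when remission is off."""
        p = short_params.copy()
        p.epi.p_remission_annual = 0.0
        rows = one_way_dsa(p, life_table, [DsaParameter("util.u_remission", 0.74, 1.0)])
        assert rows[0].icer_at_low == pytest.approx(rows[0].icer_at_high, rel=1e-12)

    def test_icer_monotone_in_ed_bundle_costs(self, life_table, short_params):
        """Raising avoided ED costs makes watchful waiting save more per
        QALY lost, so the ICER rises with ambulance and ED-visit costs."""
        for path in ("cost.ambulance_cost", "cost.ed_visit_medical_cost"):
            icers = [
                base_case(with_override(short_params, path, v), life_table).icer
                for v in (300.0, 600.0, 900.0)
            ]
            assert icers[0] < icers[1] < icers[2]

    def test_derived_parameter_override_is_preserved(self, short_params):
        p = with_override(short_params, "cost.epi_cost_immediate_ed", 0.80)
        assert p.cost.epi_cost_immediate_ed == 0.80
        # base fields that define it are untouched
        assert p.cost.p_eai_before_ed == 0.54

    def test_probability_bounds_clamped(self, short_params):
        p = with_override(short_params, "util.u_food_allergy", 1.4)
        assert p.util.u_food_allergy == 1.0

    def test_default_spec_bounds_are_ordered(self, base_params):
        for item in default_dsa_spec(base_params):
            assert item.low < item.high


class TestPsaSampling:
    def test_point_masses_reproduce_base_case(self, base_params):
        rng = np.random.default_rng(0)
        dists = {
            "epi.p_severe_annual": ParamDistribution("fixed", 0.087),
            "epi.p_has_eai": ParamDistribution("fixed", 1 - 0.094),
            "cost.hosp_total_cost": ParamDistribution("fixed", 1866.0 * 2.1),
            "cost.hosp_los_days": ParamDistribution("fixed", 2.1),
            "cost.ed_wait_hours": ParamDistribution("fixed", 3.6),
        }
        draw = sample_psa_draw(dists, rng, base=base_params)
        for key, value in base_params.to_flat_dict().items():
            got = draw.to_flat_dict()[key]
            if isinstance(value, float):
                assert got == pytest.approx(value), key
            else:
                assert got == value, key

    def test_same_rng_state_gives_identical_draw(self, base_params):
        a = sample_psa_draw(psa_distributions(), np.random.default_rng(42), base_params)
        b = sample_psa_draw(psa_distributions(), np.random.default_rng(42), base_params)
        assert a.to_flat_dict() == b.to_flat_dict()

    def test_biphasic_mean_matches_beta(self, base_params):
        """Empirical mean of the biphasic probability over many draws
        approaches 184/(184+3806)."""
        rng = np.random.default_rng(7)
        dists = {"epi.p_biphasic": ParamDistribution("beta", 184, 3806)}
        draws = np.array(
            [sample_psa_draw(dists, rng, base_params).epi.p_biphasic
             for _ in range(10_000)]
        )
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 184 / 3990) < 3 * se

    def test_draws_satisfy_invariants(self, base_params):
        rng = np.random.default_rng(5)
        dists = psa_distributions()
        for _ in range(200):
            sample_psa_draw(dists, rng, base_params).validate()

    def test_mismatched_hospital_pair_rejected(self, base_params):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            sample_psa_draw(
                {"cost.hosp_total_cost": ParamDistribution("fixed", 3000.0)},
                rng, base_params,
            )


class TestRunPsa:
    def test_seed_reproducibility_bitwise(self, life_table, short_params):
        a = run_psa(short_params, life_table, n=5, seed=9)
        b = run_psa(short_params, life_table, n=5, seed=9)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_single_iteration_equals_single_draw(self, life_table, short_params):
        psa = run_psa(short_params, life_table, n=1, seed=4)
        draw = sample_psa_draw(
            psa_distributions(), np.random.default_rng(4), base=short_params
        )
        ww, ied = evaluate_strategies(draw, life_table)
        assert psa.ww_cost[0] == pytest.approx(ww.total_cost_discounted, rel=1e-12)
        assert psa.ied_qaly[0] == pytest.approx(ied.total_qaly_discounted, rel=1e-12)

    def test_mean_outcomes_stable_across_seeds(self, life_table, short_params):
        """Two independently seeded PSAs agree on the mean incremental cost
        within 3 Monte Carlo standard errors."""
        a = run_psa(short_params, life_table, n=120, seed=1)
        b = run_psa(short_params, life_table, n=120, seed=2)
        se = np.sqrt(a.delta_cost.var(ddof=1) / a.n_iterations
                     + b.delta_cost.var(ddof=1) / b.n_iterations)
        assert abs(a.delta_cost.mean() - b.delta_cost.mean()) < 3 * se


class TestCeac:
    def test_brute_force_recount(self, life_table, short_params):
        psa = run_psa(short_params, life_table, n=40, seed=3)
        grid = [0, 25_000, 50_000, 150_000]
        curve = ceac(psa, grid)
        for w, prob in zip(curve.wtp, curve.probability):
            manual = np.mean(
                [w * dq - dc > 0 for dq, dc in zip(psa.delta_qaly, psa.delta_cost)]
            )
            assert prob == pytest.approx(manual)

    def test_empty_grid(self, life_table, short_params):
        psa = run_psa(short_params, life_table, n=3, seed=0)
        assert ceac(psa, []).wtp.size == 0

    def test_monotone_when_qaly_losses_uniform(self, life_table, short_params):
        """Watchful waiting loses QALYs in every iteration, so the CEAC is
        non-increasing in WTP."""
        psa = run_psa(short_params, life_table, n=60, seed=8)
        assert np.all(psa.delta_qaly < 0)
        curve = ceac(psa, range(0, 200_001, 25_000))
        assert np.all(np.diff(curve.probability) <= 1e-12)


class TestScenarios:
    def test_inmb_strictly_decreasing_in_fatality_multiplier(
        self, life_table, short_params
    ):
        """Common random numbers across multipliers isolate the fatality
        effect: the watchful-waiting INMB falls strictly with k."""
        inmb = []
        for k in (10, 100, 500, 1000):
            p = ScenarioSpec(f"x{k}", {"epi.ww_fatality_multiplier": float(k)}).apply(
                short_params
            )
            inmb.append(run_psa(p, life_table, n=25, seed=12).inmb_of_means)
        assert np.all(np.diff(inmb) < 0)

    def test_zero_discount_matches_undiscounted_identity(self, life_table, short_params):
        p = ScenarioSpec("d0", {"settings.discount_rate_annual": 0.0}).apply(short_params)
        ww, _ = evaluate_strategies(p, life_table)
        assert ww.total_cost_discounted == pytest.approx(ww.total_cost_undiscounted)
        assert ww.total_qaly_discounted == pytest.approx(ww.total_qaly_undiscounted)

    def test_unknown_override_key_rejected(self, short_params):
        with pytest.raises(ParameterError):
            ScenarioSpec("bad", {"epi.nonexistent": 1.0}).apply(short_params)

    def test_standard_battery_names(self):
        names = [s.name for s in scenario_specs()]
        assert names == [
            "discount_0pct", "discount_3pct", "societal_perspective",
            "fatality_100x", "fatality_500x", "fatality_1000x", "start_age_0",
        ]
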