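import dataclasses

import numpy as np
import pytest

from npcstage import cea


def no_competing_risks(params, **kw):
    return dataclasses.replace(
        params,
        mortality_annual_background=0.0,
        p_death_recurrence_cycle=0.0,
        mortality_annual_post_salvage_excess=0.0,
        **kw,
    )


class TestProbToCycle:
    def test_three_year_recurrence_conversion(self):
        p = cea.prob_to_cycle(0.2544, 3, 1)
        assert p == pytest.approx(0.09322, abs=5e-6)
        assert 1 - (1 - p) ** 3 == pytest.approx(0.2544, abs=1e-12)

    def test_zero_probability_stays_zero(self):
        assert cea.prob_to_cycle(0.0, 5, 1) == 0.0

    def test_identity_when_cycle_equals_horizon(self):
        assert cea.prob_to_cycle(0.3, 2.5, 2.5) == pytest.approx(0.3)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            cea.prob_to_cycle(1.0, 3, 1)


class TestDecisionTree:
    def test_branch_probabilities_sum_to_one(self, base_params):
        for strategy in ("pet", "mri"):
            branches = cea.build_decision_tree(base_params, strategy)
            assert sum(b.probability for b in branches) == pytest.approx(1.0, abs=1e-12)

    def test_fn_branch_probability_base_case(self, base_params):
        branches = {b.label: b for b in cea.build_decision_tree(base_params, "pet")}
        assert branches["fn"].probability == pytest.approx(0.691 * 0.040, abs=1e-12)
        assert branches["fn"].arm is cea.Arm.UPPER_NECK_ONLY and branches["fn"].diseased

    def test_perfect_test_leaves_only_tp_tn(self, base_params):
        p = dataclasses.replace(base_params, pet_sensitivity=1.0, pet_specificity=1.0)
        branches = {b.label: b.probability for b in cea.build_decision_tree(p, "pet")}
        assert branches["fn"] == branches["fp"] == 0.0
        assert branches["tp"] == pytest.approx(p.prevalence)
        assert branches["tn"] == pytest.approx(1 - p.prevalence)


class TestMarkovTrace:
    def test_undiscounted_perfect_health_gives_horizon_qalys(self, base_params):
        params = no_competing_risks(
            base_params, p_recur_3yr_treated=0.0, discount_rate=0.0,
            utility_rf_upper=1.0,
        )
        branch = cea.Branch("tn", 1.0, cea.Arm.UPPER_NECK_ONLY, False)
        trace = cea.run_markov_trace(branch, params)
        assert trace.discounted_qaly == pytest.approx(10.0, abs=1e-12)

    def test_discounted_qalys_match_geometric_series(self, base_params):
        # end-of-cycle accrual (no half-cycle correction), 3%/year
        params = no_competing_risks(
            base_params, p_recur_3yr_treated=0.0, utility_rf_upper=1.0,
            half_cycle_correction=False,
        )
        branch = cea.Branch("tn", 1.0, cea.Arm.UPPER_NECK_ONLY, False)
        trace = cea.run_markov_trace(branch, params)
        expected = sum(1.03 ** -t for t in range(1, 11))
        assert trace.discounted_qaly == pytest.approx(expected, abs=1e-12)

    def test_fn_branch_three_cycle_recurrence_round_trip(self, base_params):
        params = no_competing_risks(base_params, horizon_years=3.0)
        branch = cea.Branch("fn", 1.0, cea.Arm.UPPER_NECK_ONLY, True)
        trace = cea.run_markov_trace(branch, params)
        assert trace.cumulative_recurrence[3] == pytest.approx(0.2544, abs=1e-9)

    def test_occupancy_conserved_and_death_monotone(self, base_params):
        for label, arm, diseased in (("fn", cea.Arm.UPPER_NECK_ONLY, True),
                                     ("fp", cea.Arm.WHOLE_NECK, False)):
            trace = cea.run_markov_trace(cea.Branch(label, 1.0, arm, diseased), base_params)
            sums = trace.occupancy.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)
            dead = trace.occupancy[:, cea.State.DEAD]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_discounted_qalys_bounded_by_horizon(self, base_params):
        for branch in cea.build_decision_tree(base_params, "pet"):
            trace = cea.run_markov_trace(branch, base_params)
            assert 0 <= trace.discounted_qaly <= base_params.horizon_years


class TestStrategies:
    def test_icer_equals_hand_computed_ratio(self, base_params):
        res = cea.evaluate_strategies(base_params)
        o = res.outcomes
        by_hand = (o["pet"].cost - o["mri"].cost) / (o["pet"].qaly - o["mri"].qaly)
        assert res.icer == pytest.approx(by_hand, abs=1e-9)

    def test_printed_base_case_pairs_reproduce_published_icer(self):
        assert cea.icer_from_pairs(27228.0, 25596.0, 5.329, 5.305) \
            == pytest.approx(68000.0, abs=1e-6)

    def test_identical_strategies_give_undefined_icer(self, base_params):
        p = dataclasses.replace(
            base_params,
            mri_sensitivity=base_params.pet_sensitivity,
            mri_specificity=base_params.pet_specificity,
            cost_test_mri=base_params.cost_test_pet,
        )
        res = cea.evaluate_strategies(p)
        assert res.incremental_cost == pytest.approx(0.0, abs=1e-9)
        assert res.incremental_qaly == pytest.approx(0.0, abs=1e-12)
        assert res.icer is None
        # net-benefit comparison still reported
        assert res.nmb("pet", 1e5) == pytest.approx(res.nmb("mri", 1e5), abs=1e-6)

    def test_raising_pet_sensitivity_never_lowers_pet_qalys(self, base_params):
        qalys = []
        for sens in np.linspace(0.90, 0.999, 12):
            p = dataclasses.replace(base_params, pet_sensitivity=float(sens))
            qalys.append(cea.evaluate_strategy(p, "pet").qaly)
        assert all(b >= a - 1e-12 for a, b in zip(qalys, qalys[1:]))

    def test_equal_recurrence_and_neutral_toxicity_remove_qaly_gap(self, base_params):
        # attribute all benefit to avoided undertreatment: once the missed-
        # metastasis recurrence penalty and the whole-neck utility decrement
        # are switched off, sensitivity differences carry no QALY advantage
        p = dataclasses.replace(
            base_params,
            p_recur_3yr_fn=base_params.p_recur_3yr_treated,
            utility_rf_whole=base_params.utility_rf_upper,
            cost_test_mri=base_params.cost_test_pet,
        )
        res = cea.evaluate_strategies(p)
        assert res.incremental_qaly == pytest.approx(0.0, abs=1e-12)

    def test_costs_scale_linearly_under_uniform_cost_scaling(self, base_params):
        res1 = cea.evaluate_strategies(base_params)
        scaled = dataclasses.replace(
            base_params,
            **{name: getattr(base_params, name) * 2 for name in (
                "cost_test_mri", "cost_test_pet", "cost_rt_upper", "cost_rt_whole",
                "cost_recurrence_cycle", "cost_followup_annual", "cost_post_salvage_annual")},
        )
        res2 = cea.evaluate_strategies(scaled)
        for s in ("pet", "mri"):
            assert res2.outcomes[s].cost == pytest.approx(2 * res1.outcomes[s].cost, rel=1e-12)
            assert res2.outcomes[s].qaly == pytest.approx(res1.outcomes[s].qaly, abs=1e-12)


class TestTornado:
    def test_zero_width_range_gives_zero_width_bar(self, base_params):
        df = cea.tornado(base_params, {"prevalence": (0.691, 0.691)})
        assert df.loc[0, "icer_at_low"] == pytest.approx(df.loc[0, "icer_at_high"])
        assert df.loc[0, "bar_width"] == pytest.approx(0.0)

    def test_inert_parameter_leaves_icer_unchanged(self, base_params):
        # prevalence_low only delimits the reporting range; it is not in the model
        df = cea.tornado(base_params, {"prevalence_low": (0.6, 0.65)})
        base = cea.evaluate_strategies(base_params).icer
        assert df.loc[0, "icer_at_low"] == pytest.approx(base)
        assert df.loc[0, "icer_at_high"] == pytest.approx(base)

    def test_prevalence_range_keeps_icer_below_wtp(self, base_params):
        df = cea.tornado(base_params, {"prevalence": (0.632, 0.796)})
        assert df.loc[0, "icer_at_low"] <= base_params.wtp
        assert df.loc[0, "icer_at_high"] <= base_params.wtp

    def test_bars_sorted_by_width_and_range_must_bracket_base(self, base_params):
        df = cea.tornado(base_params)
        widths = df["bar_width"].to_numpy()
        assert all(widths[i] >= widths[i + 1] for i in range(len(widths) - 1))
        with pytest.raises(ValueError, match="bracket"):
            cea.tornado(base_params, {"prevalence": (0.75, 0.80)})


class TestPSA:
    def test_same_seed_reproduces_result(self, base_params):
        a = cea.psa(base_params, n_iter=40, seed=11)
        b = cea.psa(base_params, n_iter=40, seed=11)
        assert a.draws.equals(b.draws) and a.acceptability.equals(b.acceptability)

    def test_degenerate_distributions_reproduce_base_case(self, base_params):
        dists = {
            "prevalence": cea.ParamDistribution("beta", 0.691, 0.691, 0.691),
            "cost_test_pet": cea.ParamDistribution("gamma", 1700.0, 1700.0, 1700.0),
        }
        res = cea.psa(base_params, distributions=dists, n_iter=5, seed=0)
        base = cea.evaluate_strategies(base_params)
        assert np.allclose(res.draws["incremental_qaly"], base.incremental_qaly)
        assert np.allclose(res.draws["incremental_cost"], base.incremental_cost)
        # at WTP above the base ICER every iteration favours the dearer strategy
        above = res.acceptability.loc[
            res.acceptability.wtp > base.icer, "p_pet_cost_effective"]
        assert (above == 1.0).all()

    def test_acceptability_monotone_when_qaly_gain_universal(self, base_params):
        # cost-only uncertainty leaves the (positive) QALY gain fixed across
        # iterations, so NMB(PET) - NMB(MRI) is increasing in WTP per draw and
        # the acceptability curve must be non-decreasing
        dists = {
            name: cea.ParamDistribution("gamma", getattr(base_params, name),
                                        getattr(base_params, name) * 0.5,
                                        getattr(base_params, name) * 1.5)
            for name in ("cost_test_pet", "cost_rt_whole", "cost_recurrence_cycle")
        }
        res = cea.psa(base_params, distributions=dists, n_iter=150, seed=4)
        assert (res.draws["incremental_qaly"] > 0).all()
        acc = res.acceptability["p_pet_cost_effective"].to_numpy()
        assert all(acc[i] <= acc[i + 1] + 1e-12 for i in range(len(acc) - 1))

    def test_unknown_parameter_distribution_rejected(self, base_params):
        with pytest.raises(ValueError, match="unknown parameter"):
            cea.psa(base_params,
                    distributions={"nope": cea.ParamDistribution("beta", 0.5, 0.4, 0.6)},
                    n_iter=2, seed=0)

    def test_beta_range_outside_unit_interval_rejected(self, base_params):
        with pytest.raises(ValueError):
            cea.psa(base_params,
                    distributions={"prevalence": cea.ParamDistribution("beta", 0.9, 0.8, 1.2)},
                    n_iter=2, seed=0)
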