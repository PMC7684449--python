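import numpy as np
import pytest

from her2cea import (
    HealthState,
    LifeTable,
    build_branches,
    evaluate_strategy,
    run_branch,
    toxicity_probs,
    transition_matrix,
)
from her2cea.cohort_model import DEAD, N_STATES
from her2cea.hazards import median_survival_to_annual_prob
from her2cea.parameters import ModelSettings


def _strategy(strategies, sid):
    return next(s for s in strategies if s.id == sid)


class TestBuildBranches:
    def test_strategy3_weights_and_costs(self, strategies, params):
        pcr, residual = build_branches(_strategy(strategies, 3), params)
        assert pcr.weight == pytest.approx(0.458)
        assert residual.weight == pytest.approx(0.542)
        assert residual.upfront_cost == pytest.approx(65_428 + 199_230)
        assert pcr.upfront_cost == pytest.approx(65_428 + 108_995)

    def test_tchp_uses_post_tchp_adjuvant_costs(self, strategies, params):
        pcr, residual = build_branches(_strategy(strategies, 5), params)
        assert pcr.upfront_cost == pytest.approx(153_257 + 93_424)
        assert residual.upfront_cost == pytest.approx(153_257 + 135_318)

    def test_recurrence_risks_compose_reference_and_rr(self, strategies, params):
        pcr, residual = build_branches(_strategy(strategies, 3), params)
        ref = 1 - (1 - params.dr3y_ref) ** (1 / 3)
        assert pcr.p_dr_annual == pytest.approx(0.18 * ref)
        assert residual.p_dr_annual == pytest.approx(0.40 * ref)

    def test_residual_h_is_lr_reference(self, strategies, params):
        _, residual1 = build_branches(_strategy(strategies, 1), params)
        _, residual2 = build_branches(_strategy(strategies, 2), params)
        assert residual1.p_lr_annual == pytest.approx(
            residual2.p_lr_annual / params.rr_lr
        )

    def test_certain_pcr_empties_residual_branch(self, strategies, params):
        p = params.with_value("pcr_prob.THP", 1.0)
        pcr, residual = build_branches(_strategy(strategies, 3), p)
        assert pcr.weight == 1.0 and residual.weight == 0.0


class TestToxicityProbs:
    def test_classes(self, params):
        chf_ac, aml_ac = toxicity_probs("ac", params)
        assert chf_ac == pytest.approx(0.037 * 1.26)
        assert aml_ac == pytest.approx(0.001 * 1.68)
        chf_non, aml_non = toxicity_probs("non_ac", params)
        assert chf_non == pytest.approx(0.037)
        assert aml_non == pytest.approx(0.001 * 0.88)
        chf_no, aml_no = toxicity_probs("no_chemo", params)
        assert chf_no == 0.0
        assert aml_no == pytest.approx(0.001)

    def test_unknown_class(self, params):
        with pytest.raises(ValueError):
            toxicity_probs("weekly", params)


class TestTransitionMatrix:
    def test_rows_stochastic(self, strategies, params, life_table):
        for sid in (1, 3, 5):
            for branch in build_branches(_strategy(strategies, sid), params):
                M = transition_matrix(branch, params, life_table, 49, 0)
                assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
                assert (M >= 0).all()

    def test_death_states_absorbing(self, strategies, params, life_table):
        branch = build_branches(_strategy(strategies, 3), params)[1]
        M = transition_matrix(branch, params, life_table, 60, 5)
        for s in DEAD:
            assert M[s, s] == 1.0

    def test_dr_death_rate_from_median_survival(self, strategies, params,
                                                zero_mortality_life_table):
        branch = build_branches(_strategy(strategies, 3), params)[1]
        M = transition_matrix(branch, params, zero_mortality_life_table, 49, 0)
        expected = median_survival_to_annual_prob(38)
        assert M[HealthState.DISTANT_RECURRENCE, HealthState.DEATH_BC] == \
            pytest.approx(expected)
        assert expected == pytest.approx(0.1966, abs=5e-5)

    def test_first_cycle_mode_gates_toxicity(self, strategies, params, life_table):
        branch = build_branches(_strategy(strategies, 2), params)[1]
        RF = HealthState.RECURRENCE_FREE
        M1 = transition_matrix(branch, params, life_table, 49, 0, "first_cycle")
        M2 = transition_matrix(branch, params, life_table, 50, 1, "first_cycle")
        assert M1[RF, HealthState.AML] > 0 and M1[RF, HealthState.CHF] > 0
        assert M2[RF, HealthState.AML] == 0 and M2[RF, HealthState.CHF] == 0
        # default (lifetime) mode keeps the hazard on in later cycles
        M3 = transition_matrix(branch, params, life_table, 50, 1, "lifetime")
        assert M3[RF, HealthState.AML] > 0 and M3[RF, HealthState.CHF] > 0


class TestRunBranch:
    def test_degenerate_no_event_closed_form(self, strategies, degenerate_params,
                                             zero_mortality_life_table):
        settings = ModelSettings(discount_rate=0.0)
        branch = build_branches(_strategy(strategies, 4), degenerate_params)[0]
        # HP pCR branch: no chemotherapy toxicity, all risks zeroed
        trace = run_branch(branch, degenerate_params, settings,
                           zero_mortality_life_table)
        assert trace.total_qalys == pytest.approx(0.79 + 50 * 0.83, abs=1e-9)
        assert trace.total_cost == pytest.approx(branch.upfront_cost)

    def test_degenerate_discounted_annuity(self, strategies, degenerate_params,
                                           zero_mortality_life_table):
        settings = ModelSettings(discount_rate=0.03)
        branch = build_branches(_strategy(strategies, 4), degenerate_params)[0]
        trace = run_branch(branch, degenerate_params, settings,
                           zero_mortality_life_table)
        # independent closed form: utilities discounted mid-cycle
        k = np.arange(51)
        util = np.where(k == 0, 0.79, 0.83)
        expected = float(np.sum(util * 1.03 ** (-(k + 0.5))))
        assert trace.total_qalys == pytest.approx(expected, abs=1e-9)

    def test_trace_rows_sum_to_one(self, strategies, params, settings, life_table):
        for spec in strategies:
            for branch in build_branches(spec, params):
                trace = run_branch(branch, params, settings, life_table)
                assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_absorbing_occupancy_nondecreasing(self, strategies, params, settings,
                                               life_table):
        branch = build_branches(_strategy(strategies, 1), params)[1]
        trace = run_branch(branch, params, settings, life_table)
        dead = trace.occupancy[:, list(DEAD)].sum(axis=1)
        assert np.all(np.diff(dead) >= -1e-12)

    def test_discounted_not_above_undiscounted(self, strategies, params, settings,
                                               life_table):
        branch = build_branches(_strategy(strategies, 3), params)[1]
        trace = run_branch(branch, params, settings, life_table)
        assert np.all(trace.qaly_disc <= trace.qaly + 1e-12)
        assert np.all(trace.cost_disc <= trace.cost + 1e-12)

    def test_trace_csv_roundtrip(self, strategies, params, settings, life_table,
                                 tmp_path):
        branch = build_branches(_strategy(strategies, 3), params)[0]
        trace = run_branch(branch, params, settings, life_table)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == settings.n_cycles
        assert df.loc[0, "recurrence_free"] == 1.0


class TestEvaluateStrategy:
    def test_headline_dominance(self, base_results):
        by_id = {r.strategy_id: r for r in base_results}
        s3 = by_id[3]
        assert all(s3.qalys > r.qalys for i, r in by_id.items() if i != 3)
        assert all(s3.cost < r.cost for i, r in by_id.items() if i != 3)

    def test_certain_pcr_makes_strategies_identical(self, strategies, params,
                                                    settings, life_table):
        # strategies 1 and 2 share neoadjuvant DDAC/THP and pCR-branch H
        p = params.with_value("pcr_prob.DDAC_THP", 1.0)
        r1 = evaluate_strategy(_strategy(strategies, 1), p, settings, life_table)
        r2 = evaluate_strategy(_strategy(strategies, 2), p, settings, life_table)
        assert r1.cost == pytest.approx(r2.cost)
        assert r1.qalys == pytest.approx(r2.qalys)

    def test_monotone_in_recurrence_risk(self, strategies, params, settings,
                                         life_table):
        spec = _strategy(strategies, 3)
        base = evaluate_strategy(spec, params, settings, life_table)
        worse = evaluate_strategy(
            spec, params.with_value("rr_dr.DDAC_TDM1", 0.55), settings, life_table
        )
        assert worse.qalys < base.qalys

    def test_monotone_in_cost(self, strategies, params, settings, life_table):
        spec = _strategy(strategies, 3)
        base = evaluate_strategy(spec, params, settings, life_table)
        pricier = evaluate_strategy(
            spec, params.with_value("cost_dr_annual", 180_948.0), settings, life_table
        )
        assert pricier.cost > base.cost
        assert pricier.qalys == pytest.approx(base.qalys)

    def test_discounting_reduces_qalys(self, strategies, params, settings,
                                       life_table):
        spec = _strategy(strategies, 3)
        undisc = ModelSettings(discount_rate=0.0, toxicity_mode=settings.toxicity_mode)
        r0 = evaluate_strategy(spec, params, undisc, life_table)
        r3 = evaluate_strategy(spec, params, settings, life_table)
        assert r0.qalys >= r3.qalys


class TestLifeTable:
    def test_csv_roundtrip(self, life_table, tmp_path):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        back = LifeTable.from_csv(path)
        assert np.array_equal(back.ages, life_table.ages)
        assert np.allclose(back.qx, life_table.qx)

    def test_out_of_range_age_rejected(self, life_table):
        with pytest.raises(ValueError):
            life_table.q(500)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            LifeTable(ages=np.arange(3), qx=np.array([0.1, 1.5, 0.2]))
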