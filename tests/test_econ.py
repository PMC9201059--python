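import dataclasses

import numpy as np
import pytest

from mbcea.config import EconomicSettings, UtilitySet
from mbcea.econ import (
    ArmOutcome,
    accumulate,
    build_trace,
    cea_table,
    compute_icer,
    discount_factor,
    evaluate,
    state_cycle_cost,
    trace_table,
)
from mbcea.markov import MarkovTrace
from mbcea.sensitivity import set_parameter
from mbcea.survival import StateMembership


class TestDiscounting:
    def test_baseline_and_zero_rate(self):
        assert discount_factor(0.03, 0) == 1.0
        assert discount_factor(0.0, 57) == 1.0

    def test_one_year_discount(self):
        assert discount_factor(0.03, 12) == pytest.approx(1 / 1.03, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discount_factor(-1.5, 3)
        with pytest.raises(ValueError):
            discount_factor(0.03, -1)

    def test_discounted_total_never_exceeds_undiscounted(self, config):
        trace = build_trace(config.tib, config)
        discounted = accumulate(trace, config.tib, config.utilities,
                                config.settings)
        flat = accumulate(trace, config.tib, config.utilities,
                          dataclasses.replace(config.settings,
                                              annual_discount_rate=0.0))
        assert discounted.total_cost <= flat.total_cost
        assert discounted.total_qaly <= flat.total_qaly


class TestStateCycleCost:
    def test_triplet_event_free_on_treatment(self, config):
        # 2803.73 + 185.63 + 43.96 + 10.09: the printed state total is
        # 3,043.40 after the authors' rounding
        cost = state_cycle_cost(config.tib, "efs", 3)
        assert cost == pytest.approx(3043.41, abs=1e-9)
        assert cost == pytest.approx(3043.40, abs=0.02)

    def test_triplet_event_free_beyond_treatment_cap(self, config):
        assert state_cycle_cost(config.tib, "efs", 13) == pytest.approx(229.59)

    def test_progression_and_death_states(self, config):
        assert state_cycle_cost(config.ti, "pd", 40) == pytest.approx(305.67)
        for cycle in (0, 60):
            assert state_cycle_cost(config.tib, "dead", cycle) == 0.0

    def test_unknown_state_rejected(self, config):
        with pytest.raises(ValueError):
            state_cycle_cost(config.tib, "toxic", 1)


def _pinned_efs_trace(n_cycles: int) -> MarkovTrace:
    ones = np.ones(n_cycles)
    zeros = np.zeros(n_cycles)
    return MarkovTrace(cycles=np.arange(n_cycles), efs=ones, pd=zeros,
                       dead=zeros, terminal_cycle=n_cycles - 1,
                       termination_reason="horizon",
                       end_state=StateMembership(n_cycles, 1.0, 0.0, 0.0))


class TestAccumulate:
    def test_zero_costs_and_utilities_annihilate(self, config):
        arm = dataclasses.replace(
            config.tib, drug_components=None, drug_cost_per_cycle=0.0,
            second_line_cost_per_cycle=0.0, hospitalization_cost_per_cycle=0.0,
            ae_cost_per_cycle=0.0, tests_cost_per_cycle=0.0)
        utilities = UtilitySet(0.0, 0.0, 0.0)
        trace = build_trace(config.tib, config)
        out = accumulate(trace, arm, utilities, config.settings)
        assert out.total_cost == 0.0 and out.total_qaly == 0.0

    def test_one_year_event_free_yields_the_efs_utility(self, config):
        settings = EconomicSettings(annual_discount_rate=0.0)
        out = accumulate(_pinned_efs_trace(12), config.tib, config.utilities,
                         settings)
        assert out.total_qaly == pytest.approx(0.89, rel=1e-12)

    @pytest.mark.parametrize("mode", ["transition", "partitioned"])
    @pytest.mark.parametrize("half_cycle", [False, True])
    def test_matches_cycle_by_cycle_oracle(self, config, mode, half_cycle):
        """Vectorized totals equal a brute-force per-cycle summation."""
        cfg = dataclasses.replace(
            config, structural_mode=mode,
            settings=dataclasses.replace(config.settings,
                                         half_cycle_correction=half_cycle))
        for arm in (cfg.tib, cfg.ti):
            trace = build_trace(arm, cfg)
            out = accumulate(trace, arm, cfg.utilities, cfg.settings)
            c_efs = c_pd = u_efs = u_pd = 0.0
            occ_efs = list(trace.efs) + [trace.end_state.efs]
            occ_pd = list(trace.pd) + [trace.end_state.pd]
            for k in range(len(trace)):
                if half_cycle:
                    efs_k = 0.5 * (occ_efs[k] + occ_efs[k + 1])
                    pd_k = 0.5 * (occ_pd[k] + occ_pd[k + 1])
                else:
                    efs_k, pd_k = occ_efs[k], occ_pd[k]
                d = discount_factor(cfg.settings.annual_discount_rate, k)
                c_efs += efs_k * state_cycle_cost(arm, "efs", k) * d
                c_pd += pd_k * state_cycle_cost(arm, "pd", k) * d
                u_efs += efs_k * cfg.utilities.u_efs / 12 * d
                u_pd += pd_k * cfg.utilities.u_pd / 12 * d
            assert out.c_efs == pytest.approx(c_efs, abs=1e-9)
            assert out.c_pd == pytest.approx(c_pd, abs=1e-9)
            assert out.u_efs_total == pytest.approx(u_efs, abs=1e-12)
            assert out.u_pd_total == pytest.approx(u_pd, abs=1e-12)

    def test_decomposition_identities(self, config):
        result = evaluate(config)
        for out in (result.intervention, result.comparator):
            assert out.total_cost == out.c_efs + out.c_pd
            assert out.total_qaly == out.u_efs_total + out.u_pd_total

    def test_trace_table_sums_to_totals(self, config):
        trace = build_trace(config.tib, config)
        table = trace_table(trace, config.tib, config.utilities, config.settings)
        out = accumulate(trace, config.tib, config.utilities, config.settings)
        assert table["discounted_cost"].sum() == pytest.approx(out.total_cost)
        assert table["discounted_qaly"].sum() == pytest.approx(out.total_qaly)


def _outcome(cost: float, qaly: float) -> ArmOutcome:
    return ArmOutcome(c_efs=cost, c_pd=0.0, u_efs_total=qaly, u_pd_total=0.0)


class TestIncrementalAnalysis:
    def test_published_totals_reproduce_published_increments(self):
        result = compute_icer(_outcome(27603.420, 1.147),
                              _outcome(8786.403, 0.867))
        assert round(result.incremental_cost, 3) == 18817.017
        assert round(result.incremental_qaly, 3) == 0.280
        assert round(result.icer, 3) == 67203.632
        assert round(result.intervention.ce_ratio, 3) == 24065.754
        assert round(result.comparator.ce_ratio, 3) == 10134.260

    def test_self_comparison_has_undefined_icer(self):
        a = _outcome(100.0, 1.0)
        result = compute_icer(a, a)
        assert result.incremental_cost == 0.0
        assert result.incremental_qaly == 0.0
        assert result.icer is None
        assert result.dominance == "none"

    def test_dominant_intervention_reports_no_icer(self):
        result = compute_icer(_outcome(50.0, 2.0), _outcome(100.0, 1.0))
        assert result.dominance == "intervention_dominant"
        assert result.icer is None

    def test_dominated_intervention_reports_no_icer(self):
        result = compute_icer(_outcome(200.0, 0.5), _outcome(100.0, 1.0))
        assert result.dominance == "intervention_dominated"
        assert result.icer is None

    def test_raising_intervention_costs_raises_icer(self, config):
        base = evaluate(config).icer
        for name in ("drug_cost_bev_tib", "tests_cost_tib",
                     "second_line_cost_tib"):
            from mbcea.sensitivity import get_parameter
            bumped = set_parameter(config, name,
                                   get_parameter(config, name) * 1.1)
            assert evaluate(bumped).icer >= base

    def test_cea_table_shape_and_rounding(self, config):
        table = cea_table(evaluate(config))
        assert list(table.columns) == ["T+I+B", "T+I"]
        assert "ICER $/QALY" in table.index
        assert table.loc["Total costs", "T+I+B"] == pytest.approx(
            evaluate(config).intervention.total_cost, abs=5e-4)
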