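"""Cohort engine: closed forms, discounting, oracle equivalence, properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpcea.config import validate_config
from bpcea.engine import (
    DiscountSettings,
    StateEconomics,
    UndefinedEventReduction,
    discount_factor,
    event_reduction,
)
from bpcea.model import Model
from bpcea.states import STATE_SPACE
from bpcea.synthetic import SyntheticSpec, generate_parameter_set, generate_toy_fixture

from conftest import assert_trace_valid, enumerate_path_totals


class TestDiscountFactor:
    def test_zero_rate_is_one(self):
        assert discount_factor(7, DiscountSettings(rate=0.0)) == 1.0

    def test_start_of_cycle_first_cycle_undiscounted(self):
        assert discount_factor(0, DiscountSettings(0.05, "start_of_cycle")) == 1.0

    def test_end_of_cycle_value(self):
        d = discount_factor(1, DiscountSettings(0.05, "end_of_cycle"))
        assert d == pytest.approx(1.05**-2)
        assert d == pytest.approx(0.907029, abs=1e-6)

    def test_negative_cycle_raises(self):
        with pytest.raises(ValueError):
            discount_factor(-1, DiscountSettings())


class TestClosedForms:
    def test_two_state_geometric_life_years(self):
        """Annual death 0.1, no discounting: matches the geometric series."""
        fx = generate_toy_fixture("two_state", annual_death=0.1, horizon=60)
        trace = Model(fx.model_config()).run_strategy("toy")
        expected = sum(0.9 ** (t + 1) for t in range(60))
        assert fx.expected["total_qaly"] == pytest.approx(expected, abs=1e-12)
        assert trace.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_immortal_cohort_annuity_factor(self):
        """No deaths, 10 years at 5%: QALYs equal the annuity factor."""
        fx = generate_toy_fixture(
            "two_state", annual_death=0.0, horizon=10, discount_rate=0.05
        )
        trace = Model(fx.model_config()).run_strategy("toy")
        annuity = (1.0 - 1.05**-10) / 0.05
        assert trace.total_qaly == pytest.approx(annuity, abs=1e-9)

    def test_intervention_cost_stream(self):
        fx = generate_toy_fixture(
            "two_state", annual_death=0.05, horizon=30, discount_rate=0.03,
            intervention_cost=12.5,
        )
        trace = Model(fx.model_config()).run_strategy("toy")
        assert trace.total_cost == pytest.approx(fx.expected["total_cost"], abs=1e-9)

    def test_three_state_decrement_free_limit(self):
        """Event channel with utility 1 leaves QALYs at the two-state value."""
        two = generate_toy_fixture("two_state", annual_death=0.08, horizon=40)
        three = generate_toy_fixture(
            "three_state", annual_death=0.08, event_prob=0.05, horizon=40
        )
        t2 = Model(two.model_config()).run_strategy("toy")
        t3 = Model(three.model_config()).run_strategy("toy")
        assert t3.total_qaly == pytest.approx(t2.total_qaly, abs=1e-9)

    def test_zero_utility_everywhere_gives_zero_qalys(self):
        from bpcea.engine import run_cohort

        fx = generate_toy_fixture("three_state", annual_death=0.05, horizon=20)
        model = Model(fx.model_config())
        econ = model.economics_for("toy")
        zeroed = StateEconomics(
            state_cost=econ.state_cost,
            utility={s: 0.0 for s in STATE_SPACE.states},
            intervention_annual_cost=econ.intervention_annual_cost,
        )
        trace = run_cohort(
            _provider(model), zeroed, model.discount, model.run_settings
        )
        assert trace.total_qaly == 0.0


def _provider(model):
    from bpcea.transitions import build_transition_matrix

    tm = model.transition_model

    def provider(age, t):
        return build_transition_matrix(tm, age, between_band=model.between_band)

    return provider


class TestOracleEquivalence:
    @pytest.mark.parametrize("horizon", [10, 16])
    def test_totals_match_path_enumeration(self, horizon):
        """Engine totals equal brute-force enumeration over state paths.

        Uses a model whose reachable transient states are disease-free plus
        one acute/chronic pair (3 transient states), with nonzero costs,
        utilities and discounting, including recurrence.
        """
        fx = generate_toy_fixture(
            "three_state", annual_death=0.07, event_prob=0.06, horizon=horizon,
            discount_rate=0.04,
        )
        cfg = fx.config
        cfg["economics"]["acute_cost"]["other_ihd"]["value"] = 1000.0
        cfg["economics"]["chronic_annual_cost"]["other_ihd"]["value"] = 250.0
        cfg["economics"]["utilities"]["acute_other_ihd"] = 0.6
        cfg["economics"]["utilities"]["chronic_other_ihd"] = 0.8
        model = Model(validate_config(cfg))
        trace = model.run_strategy("toy")

        M = _provider(model)(40.0, 0)
        econ = model.economics_for("toy")
        utilities = econ.utility_vector()
        costs = econ.cost_vector() + econ.intervention_annual_cost * econ.intervention_mask()
        q, c = enumerate_path_totals(
            [M] * horizon,
            utilities,
            costs,
            rate=0.04,
            n_cycles=horizon,
            absorbing=set(STATE_SPACE.absorbing_indices),
        )
        assert trace.total_qaly == pytest.approx(q, abs=1e-9)
        assert trace.total_cost == pytest.approx(c, abs=1e-9)


class TestEventReduction:
    def test_identical_traces_give_zero(self, default_model):
        a = default_model.run_strategy("none")
        assert event_reduction(a, a) == 0.0

    def test_complete_prevention_gives_one(self):
        fx_base = generate_toy_fixture(
            "three_state", annual_death=0.05, event_prob=0.02, horizon=30
        )
        fx_none = generate_toy_fixture(
            "three_state", annual_death=0.05, event_prob=0.0, horizon=30
        )
        base = Model(fx_base.model_config()).run_strategy("toy")
        prevented = Model(fx_none.model_config()).run_strategy("toy")
        assert event_reduction(prevented, base) == pytest.approx(1.0)

    def test_matches_per_cycle_bookkeeping(self):
        """HR 0.9 on a single 1%-per-year event channel over 10 years."""
        p = 0.01
        p_tr = 1.0 - 0.99**0.9  # rate-domain application of HR 0.9
        years = 10

        def expected_incidence(p_annual):
            alive_free, inc = 1.0, 0.0
            for _ in range(years):
                inc += alive_free * p_annual
                alive_free *= 1.0 - p_annual
            return inc

        fx_base = generate_toy_fixture(
            "three_state", annual_death=0.0, event_prob=p, horizon=years
        )
        fx_tr = generate_toy_fixture(
            "three_state", annual_death=0.0, event_prob=p_tr, horizon=years
        )
        base = Model(fx_base.model_config()).run_strategy("toy")
        treated = Model(fx_tr.model_config()).run_strategy("toy")
        assert base.lifetime_first_event_incidence == pytest.approx(
            expected_incidence(p), abs=1e-12
        )
        assert event_reduction(treated, base) == pytest.approx(
            (expected_incidence(p) - expected_incidence(p_tr)) / expected_incidence(p),
            abs=1e-12,
        )

    def test_zero_comparator_incidence_signalled(self):
        fx = generate_toy_fixture("two_state", annual_death=0.05, horizon=10)
        trace = Model(fx.model_config()).run_strategy("toy")
        with pytest.raises(UndefinedEventReduction):
            event_reduction(trace, trace)


class TestProperties:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mass_conservation_and_monotone_absorption(self, seed):
        cfg = validate_config(generate_parameter_set(SyntheticSpec(seed=seed)))
        trace = Model(cfg).run_strategy("combination")
        assert_trace_valid(trace)

    def test_discounting_monotonicity(self):
        """Zero rate equals undiscounted sums; higher rates never increase totals."""
        cfg = generate_parameter_set(SyntheticSpec(seed=3))
        totals = []
        for rate in (0.0, 0.03, 0.08):
            cfg2 = {**cfg, "run": {**cfg["run"], "discount_rate": rate}}
            trace = Model(validate_config(cfg2)).run_strategy("none")
            totals.append((trace.total_qaly, trace.total_cost))
        undiscounted_qaly = sum(
            Model(validate_config(cfg | {"run": {**cfg["run"], "discount_rate": 0.0}}))
            .run_strategy("none")
            .discounted_qaly
        )
        assert totals[0][0] == pytest.approx(undiscounted_qaly)
        assert totals[0][0] > totals[1][0] > totals[2][0]
        assert totals[0][1] > totals[1][1] > totals[2][1]

    def test_uniform_protective_effect_monotonicity(self):
        """A uniform hazard multiplier < 1 never lowers QALYs or raises incidence."""
        base_cfg = validate_config(generate_parameter_set(SyntheticSpec(seed=5)))
        base = Model(base_cfg).run_strategy("none")
        treated = Model(base_cfg).run_strategy("combination")
        assert treated.total_qaly >= base.total_qaly
        assert (
            treated.lifetime_first_event_incidence
            <= base.lifetime_first_event_incidence
        )

    def test_effect_duration_cap_brackets_none_and_full(self):
        """Capping effect duration lands between untreated and lifelong effect."""
        cfg = generate_parameter_set(SyntheticSpec(seed=1))
        full = Model(validate_config(cfg)).run_strategy("combination")
        none = Model(validate_config(cfg)).run_strategy("none")
        capped_cfg = {**cfg, "run": {**cfg["run"], "effect_duration_years": 5.0}}
        capped = Model(validate_config(capped_cfg)).run_strategy("combination")
        assert none.total_qaly < capped.total_qaly < full.total_qaly

    def test_half_cycle_correction_brackets_default(self):
        cfg = generate_parameter_set(SyntheticSpec(seed=2))
        end = Model(validate_config(cfg)).run_strategy("none")
        hc_cfg = {**cfg, "run": {**cfg["run"], "half_cycle_correction": True}}
        half = Model(validate_config(hc_cfg)).run_strategy("none")
        # half-cycle accrual averages in the (larger) pre-transition occupancy
        assert half.total_qaly > end.total_qaly
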