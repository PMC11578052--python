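"""One-way sensitivity, PSA distributions and sampling, CEAC construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpcea.cea import StrategyResult, icer
from bpcea.model import default_parameter_ranges, icer_runner, psa_runner
from bpcea.sensitivity import (
    ParameterDistribution,
    ParameterRange,
    ceac,
    derive_distribution,
    family_for_path,
    one_way,
    psa,
)


@pytest.fixture(scope="module")
def tornado(default_config):
    runner = icer_runner(default_config, "none", "salt_substitution")
    ranges = default_parameter_ranges(default_config)
    return runner, ranges, one_way(runner, ranges)


class TestOneWay:
    def test_base_value_reproduces_base_icer(self, tornado):
        runner, ranges, table = tornado
        base = table.attrs["base_icer"]
        r = ranges[0]
        assert runner({r.path: r.base}) == pytest.approx(base, rel=1e-12)

    def test_untouched_parameter_has_zero_spread(self, tornado):
        _, _, table = tornado
        row = table[table["parameter"] == "interventions.drug_treatment.annual_cost.value"]
        assert row["spread"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_sorted_by_spread_descending(self, tornado):
        _, _, table = tornado
        spreads = table["spread"].dropna().to_numpy()
        assert (np.diff(spreads) <= 1e-12).all()

    def test_salt_cost_is_widest_cost_bar(self, tornado):
        """The intervention's own annual cost dominates the cost tornado bars."""
        _, _, table = tornado
        cost_rows = table[table["parameter"].str.contains("cost")]
        assert (
            cost_rows.iloc[0]["parameter"]
            == "interventions.salt_substitution.annual_cost.value"
        )

    def test_invalid_bound_recorded_not_raised(self, default_config):
        runner = icer_runner(default_config, "none", "salt_substitution")
        bad = ParameterRange("transitions.first_event.ami.0", 0.0005, 0.001, 1.5)
        table = one_way(runner, [bad])
        row = table.iloc[0]
        assert row["icer_low"] is not None
        assert row["icer_high"] is None
        assert "high" in row["error"]

    def test_top_k_truncates(self, tornado):
        runner, ranges, _ = tornado
        table = one_way(runner, ranges, top_k=10)
        assert len(table) == 10


class TestDeriveDistribution:
    def test_beta_mean_matches_base(self):
        d = derive_distribution(ParameterRange("u", 0.4, 0.5, 0.6), "beta")
        assert d.family == "beta"
        assert d.mean() == pytest.approx(0.5, abs=1e-6)

    def test_beta_quantiles_match_range(self):
        d = derive_distribution(ParameterRange("u", 0.4, 0.5, 0.6), "beta")
        lo, hi = d.dist.ppf([0.025, 0.975])
        assert lo == pytest.approx(0.4, abs=0.01)
        assert hi == pytest.approx(0.6, abs=0.01)

    def test_gamma_quantiles_within_one_percent(self):
        d = derive_distribution(ParameterRange("c", 50.0, 100.0, 170.0), "gamma")
        lo, hi = d.dist.ppf([0.025, 0.975])
        assert lo == pytest.approx(50.0, rel=0.05)
        assert hi == pytest.approx(170.0, rel=0.05)
        assert d.mean() == pytest.approx(100.0, rel=1e-6)

    def test_lognormal_median_at_base(self):
        d = derive_distribution(ParameterRange("hr", 0.81, 0.89, 0.97), "lognormal")
        assert d.dist.median() == pytest.approx(0.89, rel=1e-9)

    def test_degenerate_range_is_point_mass(self):
        d = derive_distribution(ParameterRange("x", 2.0, 2.0, 2.0), "beta")
        assert d.family == "point"
        rng = np.random.default_rng(0)
        assert (d.sample(rng, 10) == 2.0).all()

    def test_infeasible_fit_falls_back_to_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            d = derive_distribution(ParameterRange("u", -0.5, 0.5, 2.0), "beta")
        assert d.family == "uniform"

    def test_family_inference_by_domain(self):
        assert family_for_path("economics.utilities.chronic_ami") == "beta"
        assert family_for_path("transitions.first_event.ami.0") == "beta"
        assert family_for_path("economics.acute_cost.ami.value") == "gamma"
        assert family_for_path("evidence.bp.hr.ami.0") == "lognormal"


def _fake_runner(base=None):
    base = base or {}

    def run(overrides):
        a = overrides.get("a", 1.0)
        b = overrides.get("b", 2.0)
        return {
            "x": StrategyResult("x", total_cost=100 * a, total_qaly=10.0),
            "y": StrategyResult("y", total_cost=200 * b, total_qaly=11.0),
        }

    return run


class TestPSA:
    def test_point_mass_equals_base_case(self):
        dists = [
            ParameterDistribution("a", "point", value=1.0),
            ParameterDistribution("b", "point", value=2.0),
        ]
        res = psa(_fake_runner(), dists, n_iterations=5, seed=0)
        wide = res.iterations.pivot(index="iteration", columns="strategy")
        assert (wide[("cost", "x")] == 100.0).all()
        assert (wide[("cost", "y")] == 400.0).all()

    def test_seeded_reproducibility_bitwise(self):
        dists = [
            ParameterDistribution("a", "gamma", dist=stats.gamma(4, scale=0.25)),
            ParameterDistribution("b", "lognormal", dist=stats.lognorm(0.2, scale=2.0)),
        ]
        r1 = psa(_fake_runner(), dists, n_iterations=50, seed=7)
        r2 = psa(_fake_runner(), dists, n_iterations=50, seed=7)
        pd.testing.assert_frame_equal(r1.iterations, r2.iterations)
        pd.testing.assert_frame_equal(r1.draws, r2.draws)
        r3 = psa(_fake_runner(), dists, n_iterations=50, seed=8)
        assert not r3.draws.equals(r1.draws)

    def test_sample_mean_matches_distribution_mean(self):
        """CLT check: sampled mean within 3 standard errors at n=2000."""
        dist = stats.gamma(4, scale=25.0)
        dists = [ParameterDistribution("a", "gamma", dist=dist)]
        res = psa(_fake_runner(), dists, n_iterations=2000, seed=1)
        samples = res.draws["a"].to_numpy()
        se = dist.std() / np.sqrt(len(samples))
        assert abs(samples.mean() - dist.mean()) < 3 * se

    def test_model_psa_runs_and_varies(self, default_config):
        ranges = default_parameter_ranges(default_config)[:6]
        dists = [derive_distribution(r, family_for_path(r.path)) for r in ranges]
        res = psa(psa_runner(default_config), dists, n_iterations=20, seed=3)
        assert res.iterations["strategy"].nunique() == 4
        costs = res.iterations.query("strategy == 'salt_substitution'")["cost"]
        assert costs.std() > 0


class TestCEAC:
    def test_probabilities_partition_to_one(self, default_config):
        ranges = default_parameter_ranges(default_config)[:6]
        from bpcea.sensitivity import derive_distribution as dd

        dists = [dd(r, family_for_path(r.path)) for r in ranges]
        res = psa(psa_runner(default_config), dists, n_iterations=30, seed=5)
        curve = ceac(res, [0, 5000, 10264.8, 20000, 50000])
        sums = curve.table.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert ((curve.table.to_numpy() >= 0) & (curve.table.to_numpy() <= 1)).all()

    def test_point_mass_two_strategy_step_at_icer(self):
        """Deterministic PSA: the CEAC is a step function at the pairwise ICER."""
        x = StrategyResult("x", total_cost=100.0, total_qaly=10.0)
        y = StrategyResult("y", total_cost=600.0, total_qaly=10.1)
        step = icer(x, y)  # 5000

        def runner(overrides):
            return {"x": x, "y": y}

        res = psa(runner, [ParameterDistribution("a", "point", value=1.0)], 10, seed=0)
        curve = ceac(res, [step * 0.9, step, step * 1.1])
        assert curve.probability_at("x", step * 0.9) == 1.0
        assert curve.probability_at("y", step * 1.1) == 1.0
        # exact tie at the step: probability split equally
        assert curve.probability_at("x", step) == pytest.approx(0.5)

    def test_cheapest_wins_at_zero_wtp(self, default_config):
        ranges = default_parameter_ranges(default_config)[:4]
        dists = [derive_distribution(r, family_for_path(r.path)) for r in ranges]
        res = psa(psa_runner(default_config), dists, n_iterations=20, seed=2)
        curve = ceac(res, [0.0])
        assert curve.probability_at("none", 0.0) == pytest.approx(1.0)

    def test_most_effective_strategy_curve_nondecreasing_two_strategies(self):
        rng = np.random.default_rng(11)
        costs = rng.normal([100, 400], 30, size=(40, 2))
        qalys = rng.normal([10.0, 10.2], 0.05, size=(40, 2))
        rows = []
        for it in range(40):
            rows.append({"iteration": it, "strategy": "x", "cost": costs[it, 0], "qaly": qalys[it, 0]})
            rows.append({"iteration": it, "strategy": "y", "cost": costs[it, 1], "qaly": qalys[it, 1]})
        from bpcea.sensitivity import PSAResult

        res = PSAResult(
            iterations=pd.DataFrame(rows), draws=pd.DataFrame(), seed=0, n_iterations=40
        )
        grid = np.linspace(0, 30000, 31)
        curve = ceac(res, grid)
        probs_y = curve.table["y"].to_numpy()
        assert (np.diff(probs_y) >= -1e-12).all()

    def test_empty_grid_raises(self):
        res_df = pd.DataFrame(
            [{"iteration": 0, "strategy": "x", "cost": 1.0, "qaly": 1.0},
             {"iteration": 0, "strategy": "y", "cost": 2.0, "qaly": 2.0}]
        )
        from bpcea.sensitivity import PSAResult

        res = PSAResult(iterations=res_df, draws=pd.DataFrame(), seed=0, n_iterations=1)
        with pytest.raises(ValueError):
            ceac(res, [])
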