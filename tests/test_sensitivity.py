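"""Deterministic and probabilistic sensitivity analysis."""

import numpy as np
import pytest

from glaucoma_cea import (
    ConfigurationError,
    ParameterDistribution,
    moments_to_beta,
    moments_to_gamma,
    one_way_dsa,
    random_scenario,
    run_base_case,
    run_psa,
    tornado,
)
from glaucoma_cea.cea import nmb
from glaucoma_cea.config import with_overrides
from glaucoma_cea.sensitivity import default_wtp_grid


class TestMethodOfMoments:
    def test_gamma_analytic_point(self):
        shape, scale = moments_to_gamma(100.0, 10.0)
        assert shape == pytest.approx(100.0)
        assert scale == pytest.approx(1.0)

    def test_beta_analytic_point(self):
        alpha, beta = moments_to_beta(0.5, 0.1)
        assert alpha == pytest.approx(12.0)
        assert beta == pytest.approx(12.0)

    @pytest.mark.parametrize("mean, se", [(250.0, 40.0), (0.3, 0.05), (0.865, 0.03)])
    def test_moments_recovered_by_sampling(self, mean, se, rng):
        """1e6 draws from the recovered parameterization reproduce the
        declared mean and SE within 3 standard errors."""
        n = 1_000_000
        if mean > 1:
            shape, scale = moments_to_gamma(mean, se)
            draws = rng.gamma(shape, scale, size=n)
        else:
            a, b = moments_to_beta(mean, se)
            draws = rng.beta(a, b, size=n)
        assert abs(draws.mean() - mean) <= 3 * se / np.sqrt(n)
        # sampling error of the SD estimate, normal approximation
        assert abs(draws.std(ddof=1) - se) <= 4 * se / np.sqrt(2 * (n - 1)) + 1e-4 * se

    def test_infeasible_beta_variance_rejected(self):
        with pytest.raises(ConfigurationError, match="infeasible beta variance"):
            moments_to_beta(0.95, 0.4)

    def test_gamma_requires_positive_mean(self):
        with pytest.raises(ConfigurationError):
            moments_to_gamma(-1.0, 1.0)

    def test_beta_distribution_for_out_of_range_mean_rejected_before_sampling(self):
        with pytest.raises(ConfigurationError):
            ParameterDistribution(name="x", kind="beta", mean=1.4, standard_error=0.05)


class TestOneWayDsa:
    def test_zero_range_reproduces_base_case_everywhere(self, ref_config):
        curve = one_way_dsa(ref_config, "cost.blind", relative_range=0.0, grid_size=5)
        assert curve.icer.nunique() == 1
        base = run_base_case(ref_config)
        assert curve.icer.iloc[0] == pytest.approx(base.cea.icer)

    def test_unused_parameter_leaves_icer_flat(self, ref_config):
        """A parameter entering neither strategy's pathway cannot move the
        ICER: with perfectly sensitive tests nobody follows the untreated
        arm, so sweeping its progression changes nothing."""
        from glaucoma_cea import ModelConfig

        doc = ref_config.to_dict()
        doc["psa"]["distributions"] = []
        for s in doc["strategies"].values():
            s["test"]["sensitivity"]["value"] = 1.0
        cfg = ModelConfig.from_dict(doc)
        curve = one_way_dsa(cfg, "natural_history.severe_to_blind", 0.2, 5)
        assert np.allclose(curve.icer, curve.icer.iloc[0], rtol=1e-12)

    def test_unknown_parameter_rejected(self, ref_config):
        with pytest.raises(ConfigurationError, match="unknown parameter"):
            one_way_dsa(ref_config, "cost.sight", 0.2, 3)

    def test_blindness_cost_direction(self, ref_config):
        """Costlier blindness favours the strategy that prevents it: the
        teleglaucoma ICER falls (more savings per QALY) as the annual cost
        of blindness rises."""
        curve = one_way_dsa(ref_config, "cost.blind", relative_range=0.2, grid_size=9)
        assert np.all(np.diff(curve.icer) < 0)
        assert np.all(np.diff(curve.incremental_nmb) > 0)


class TestTornado:
    def test_widths_match_independent_recomputation(self, ref_config):
        entries = tornado(ref_config, parameters=["prevalence", "cost.blind"])
        for e in entries:
            recomputed = []
            for value in (e.low_value, e.high_value):
                cfg = with_overrides(ref_config, {e.parameter: value})
                base = run_base_case(cfg)
                recomputed.append(
                    base.nmb(cfg.reference_strategy) - base.nmb(cfg.comparator_strategy)
                )
            assert e.range_width == pytest.approx(abs(recomputed[1] - recomputed[0]))

    def test_order_invariant_to_input_order(self, ref_config):
        params = list(ref_config.dsa.parameters)
        a = tornado(ref_config, parameters=params)
        b = tornado(ref_config, parameters=list(reversed(params)))
        assert [e.parameter for e in a] == [e.parameter for e in b]
        assert [e.range_width for e in a] == pytest.approx([e.range_width for e in b])

    def test_prevalence_dominates_reference_tornado(self, ref_config):
        """Disease prevalence carries the widest NMB swing in the reference
        set, mirroring the published ranking."""
        entries = tornado(ref_config)
        assert entries[0].parameter == "prevalence"
        assert np.all(np.diff([e.range_width for e in entries]) <= 1e-9)

    def test_empty_parameter_set_rejected(self, ref_config):
        with pytest.raises(ConfigurationError):
            tornado(ref_config, parameters=[])

    def test_fixed_swing_parameter_has_zero_width(self, ref_config):
        entries = tornado(ref_config, parameters=["cost.blind"], relative_range=0.0)
        assert entries[0].range_width == pytest.approx(0.0, abs=1e-9)


class TestPsa:
    def test_degenerate_distributions_reproduce_base_case_exactly(self, ref_config):
        """With every distribution collapsed to its mean, each draw equals
        the deterministic base case bit for bit."""
        cfg = ref_config
        doc = cfg.to_dict()
        for d in doc["psa"]["distributions"]:
            d["se"] = 0.0
        from glaucoma_cea import ModelConfig

        degenerate = ModelConfig.from_dict(doc)
        res = run_psa(degenerate, n_samples=8, seed=3)
        base = run_base_case(cfg)
        for name in res.costs:
            assert np.all(res.costs[name] == base.outcomes[name].expected_cost)
            assert np.all(res.effects[name] == base.outcomes[name].expected_qaly)

    def test_seeded_runs_bit_identical(self, ref_config):
        a = run_psa(ref_config, n_samples=40, seed=99)
        b = run_psa(ref_config, n_samples=40, seed=99)
        for name in a.costs:
            assert np.array_equal(a.costs[name], b.costs[name])
            assert np.array_equal(a.effects[name], b.effects[name])
        assert a.ceac.equals(b.ceac)

    def test_extending_sample_preserves_earlier_draws(self, ref_config):
        """Per-draw substreams: growing n keeps draws 0..n-1 unchanged."""
        short = run_psa(ref_config, n_samples=10, seed=5)
        longer = run_psa(ref_config, n_samples=25, seed=5)
        for name in short.costs:
            assert np.array_equal(longer.costs[name][:10], short.costs[name])

    def test_ceac_bounds_and_complementarity(self, ref_config):
        res = run_psa(ref_config, n_samples=60, seed=11, wtp_grid=default_wtp_grid(steps=50))
        probs = res.ceac.drop(columns="wtp")
        assert ((probs >= 0) & (probs <= 1)).all().all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        # at WTP 0 only costs matter: the (stochastically) cheaper
        # teleglaucoma strategy must be preferred in at least half the draws
        assert res.ceac.iloc[0]["p_teleglaucoma"] >= 0.5

    def test_summary_statistics_describe_stored_samples(self, ref_config):
        res = run_psa(ref_config, n_samples=50, seed=2)
        s = res.summary()
        for name in res.costs:
            assert s.loc[name, "mean_cost"] == pytest.approx(res.costs[name].mean())
            assert s.loc[name, "sd_cost"] == pytest.approx(res.costs[name].std(ddof=1))

    def test_random_scenario_psa_runs(self):
        cfg = random_scenario(7)
        res = run_psa(cfg, n_samples=20, seed=1, wtp_grid=np.linspace(0, 5e4, 11))
        assert res.n_samples == 20
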