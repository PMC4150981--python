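"""Distribution fitting, one-way/tornado analysis and the PSA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import markovcea as m
from markovcea.parameters import DistributionSpec
from markovcea.sensitivity import (
    ONE_WAY_PARAMETERS,
    one_way,
    run_psa,
    scale_parameter,
    tornado,
)


class TestFitDistribution:
    def test_gamma_method_of_moments(self):
        s = m.fit_distribution(DistributionSpec("gamma", 3312.0, 331.0))
        assert s.shape == pytest.approx((3312 / 331) ** 2, rel=1e-12)
        assert s.scale == pytest.approx(331**2 / 3312, rel=1e-12)
        assert s.shape == pytest.approx(100.12, abs=0.01)
        assert s.scale == pytest.approx(33.08, abs=0.01)

    def test_beta_method_of_moments(self):
        s = m.fit_distribution(DistributionSpec("beta", 0.71, 0.04))
        nu = 0.71 * 0.29 / 0.04**2 - 1
        assert s.alpha == pytest.approx(0.71 * nu, rel=1e-12)
        assert s.alpha == pytest.approx(90.66, abs=0.01)
        assert s.beta == pytest.approx(37.03, abs=0.01)

    def test_zero_se_is_a_point_mass(self):
        rng = np.random.default_rng(0)
        for family in ("gamma", "beta", "lognormal"):
            s = m.fit_distribution(DistributionSpec(family, 0.5, 0.0))
            assert all(s.sample(rng) == 0.5 for _ in range(5))

    def test_infeasible_beta_is_signalled(self):
        with pytest.raises(ValueError, match="infeasible"):
            m.fit_distribution(DistributionSpec("beta", 0.5, 0.6))

    def test_invalid_means_are_signalled(self):
        for family, mean in (("gamma", -1.0), ("lognormal", 0.0), ("beta", 1.5)):
            with pytest.raises(ValueError):
                m.fit_distribution(DistributionSpec(family, mean, 0.1))

    @given(
        mean=st.floats(1e-2, 1e5), rel_se=st.floats(1e-4, 2.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_gamma_and_lognormal_analytic_moments_match_the_spec(self, mean, rel_se):
        """Method of moments means what it says: the fitted distribution's
        analytic mean and SD equal the requested (mean, SE) for any
        feasible input."""
        se = mean * rel_se
        g = m.fit_distribution(DistributionSpec("gamma", mean, se))
        assert g.shape * g.scale == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(g.shape) * g.scale == pytest.approx(se, rel=1e-9)
        ln = m.fit_distribution(DistributionSpec("lognormal", mean, se))
        assert math.exp(ln.mu + ln.sigma2 / 2) == pytest.approx(mean, rel=1e-9)
        analytic_var = (math.exp(ln.sigma2) - 1) * math.exp(2 * ln.mu + ln.sigma2)
        assert math.sqrt(analytic_var) == pytest.approx(se, rel=1e-7)

    @given(mean=st.floats(0.05, 0.95), se_frac=st.floats(1e-3, 0.9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_beta_analytic_moments_match_the_spec(self, mean, se_frac):
        se = se_frac * math.sqrt(mean * (1 - mean))
        b = m.fit_distribution(DistributionSpec("beta", mean, se))
        assert b.alpha / (b.alpha + b.beta) == pytest.approx(mean, rel=1e-9)
        nu = b.alpha + b.beta
        analytic_var = mean * (1 - mean) / (nu + 1)
        assert math.sqrt(analytic_var) == pytest.approx(se, rel=1e-7)

    @pytest.mark.parametrize(
        "family, mean, se",
        [("gamma", 3312.0, 331.0), ("beta", 0.71, 0.04), ("lognormal", 2.60, 0.30)],
    )
    def test_samplers_recover_their_moments(self, family, mean, se):
        rng = np.random.default_rng(2024)
        n = 10_000
        draws = np.array(
            [m.fit_distribution(DistributionSpec(family, mean, se)).sample(rng)
             for _ in range(n)]
        )
        assert draws.mean() == pytest.approx(mean, abs=4 * se / np.sqrt(n))
        assert draws.std() == pytest.approx(se, rel=0.1)


class TestOneWay:
    def test_unknown_parameter_is_an_error(self, params):
        with pytest.raises(ValueError, match="unknown"):
            one_way(params, "cost_of_tea", sex="men", start_age=42)

    def test_unit_factors_reproduce_the_base_icer(self, params):
        res = one_way(params, "intervention_cost", sex="men", start_age=42,
                      factors=(1.0, 1.0))
        assert res.icer_at_low == pytest.approx(res.base_icer)
        assert res.icer_at_high == pytest.approx(res.base_icer)

    def test_cheaper_programme_improves_the_icer(self, params):
        res = one_way(params, "intervention_cost", sex="men", start_age=42)
        assert res.icer_at_low < res.base_icer < res.icer_at_high

    def test_stronger_effect_improves_the_icer(self, params):
        res = one_way(params, "intervention_effect", sex="men", start_age=42)
        assert res.icer_at_high < res.base_icer < res.icer_at_low

    @pytest.mark.parametrize("sex", ["men", "women"])
    def test_tornado_is_led_by_effect_then_programme_cost(
        self, params, calibrated_ages, sex
    ):
        results = tornado(params, "base", sex=sex, start_age=calibrated_ages[sex])
        assert [r.parameter for r in results[:2]] == [
            "intervention_effect",
            "intervention_cost",
        ]
        widths = [r.width for r in results]
        assert widths == sorted(widths, reverse=True)

    def test_stored_endpoints_match_an_independent_rerun(self, params):
        res = one_way(params, "cost_diabetes", sex="men", start_age=42)
        for factor, stored in ((0.70, res.icer_at_low), (1.30, res.icer_at_high)):
            rerun = m.run_comparison(
                scale_parameter(params, "cost_diabetes", factor),
                "base", sex="men", start_age=42,
            )
            assert rerun.icer.icer == stored

    def test_single_parameter_tornado(self, params):
        results = tornado(params, sex="men", start_age=42,
                          parameters=("cost_diabetes",))
        assert len(results) == 1 and results[0].parameter == "cost_diabetes"

    def test_every_declared_parameter_is_scalable(self, params):
        for name in ONE_WAY_PARAMETERS:
            scaled = scale_parameter(params, name, 1.3)
            assert m.validate(scaled) == []


class TestPSA:
    def test_needs_at_least_two_draws(self, params):
        with pytest.raises(ValueError):
            run_psa(params, n=1, sex="men", start_age=42)

    def test_same_seed_is_bit_identical(self, params):
        a = run_psa(params, n=40, seed=9, sex="men", start_age=42)
        b = run_psa(params, n=40, seed=9, sex="men", start_age=42)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.icer, b.icer)

    def test_zero_ses_reproduce_the_deterministic_base_case_exactly(self, params):
        p = params.copy()
        p.costs.state_costs = {k: (v, 0.0) for k, (v, _) in p.costs.state_costs.items()}
        p.costs.pedometer_year_se = 0.0
        p.costs.other_year_se = 0.0
        p.utilities.utilities = {k: (v, 0.0) for k, (v, _) in p.utilities.utilities.items()}
        p.effects.se_pct = {k: 0.0 for k in p.effects.se_pct}
        det = m.run_comparison(p, "base", sex="men", start_age=42)
        psa = run_psa(p, n=5, seed=3, sex="men", start_age=42)
        np.testing.assert_allclose(psa.delta_qaly, det.icer.delta_qaly, atol=1e-12)
        np.testing.assert_allclose(psa.delta_cost, det.icer.delta_cost, atol=1e-9)

    def test_credible_interval_brackets_the_mean(self, params):
        psa = run_psa(params, n=400, seed=7, sex="men", start_age=42)
        for which, mean in (("delta_qaly", psa.mean_delta_qaly),
                            ("delta_cost", psa.mean_delta_cost)):
            lo, hi = psa.credible_interval(which)
            assert lo <= mean <= hi

    def test_deterministic_point_falls_in_the_99pct_bounding_box(self, params):
        det = m.run_comparison(params, "base", sex="men", start_age=42)
        psa = run_psa(params, n=400, seed=11, sex="men", start_age=42)
        for values, point in ((psa.delta_qaly, det.icer.delta_qaly),
                              (psa.delta_cost, det.icer.delta_cost)):
            lo, hi = np.percentile(values, [0.5, 99.5])
            assert lo <= point <= hi

    def test_intervals_widen_when_all_ses_are_scaled_up(self, params):
        def width(scale):
            p = params.copy()
            p.costs.state_costs = {
                k: (v, s * scale) for k, (v, s) in p.costs.state_costs.items()
            }
            p.costs.pedometer_year_se *= scale
            p.costs.other_year_se *= scale
            p.utilities.utilities = {
                k: (v, min(s * scale, 0.9 * np.sqrt(v * (1 - v)) if v > 0 else 0.0))
                for k, (v, s) in p.utilities.utilities.items()
            }
            psa = run_psa(p, n=400, seed=21, sex="men", start_age=42)
            lo, hi = psa.credible_interval("delta_cost")
            return hi - lo

        assert width(0.5) < width(1.0) < width(2.0)

    def test_ce_plane_and_threshold_fraction(self, params):
        psa = run_psa(params, n=200, seed=5, sex="men", start_age=42)
        plane = psa.ce_plane()
        assert list(plane.columns) == ["delta_qaly", "delta_cost"]
        assert len(plane) == 200
        assert 0.0 <= psa.fraction_below_threshold <= 1.0
        summary = psa.summary()
        assert summary["n"] == 200 and summary["n_rejected"] == 0
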