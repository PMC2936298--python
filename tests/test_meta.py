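import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit
from scipy.stats import norm

import birthmix as bm
from birthmix.meta import MetaEstimate, RiskTarget
from birthmix.mixture import MixtureModel

from conftest import constant_risk_model


def meta_of(thetas, bias=0.0, j=1, x0=3000.0):
    return MetaEstimate(RiskTarget(j, x0), np.asarray(thetas, float), bias=bias)


def mixture_1():
    return MixtureModel(np.array([1.0]), np.array([3000.0]), np.array([400.0]))


class TestCombineRiskEstimates:
    def test_identical_fits_idempotent(self, scenario):
        fits = [constant_risk_model(scenario.mixture, [0.1, 0.05, 0.01, 0.02])] * 5
        m = bm.combine_risk_estimates(fits, 2, 2772.0)
        assert expit(m.theta_bar) == pytest.approx(0.05, rel=1e-12)
        assert m.s_theta == 0.0
        assert m.n_rep == 5

    def test_single_fit(self, scenario):
        fits = [constant_risk_model(scenario.mixture, [0.1, 0.05, 0.01, 0.02])]
        m = bm.combine_risk_estimates(fits, 3, 3170.0)
        assert expit(m.theta_bar) == pytest.approx(0.01, rel=1e-12)
        assert m.s_theta == 0.0

    def test_logit_antisymmetry(self, scenario):
        fits = [
            constant_risk_model(scenario.mixture, [0.2] * 4),
            constant_risk_model(scenario.mixture, [0.8] * 4),
        ]
        m = bm.combine_risk_estimates(fits, 1, 832.0)
        assert expit(m.theta_bar) == pytest.approx(0.5, abs=1e-12)

    def test_unestimated_samples_excluded(self, scenario):
        good = constant_risk_model(scenario.mixture, [0.1, 0.05, 0.01, 0.02])
        coeffs = good.coeffs.copy()
        coeffs[0] = np.nan
        partial = bm.RiskModel(scenario.mixture, coeffs, degree=4)
        with pytest.warns(RuntimeWarning, match="excluded"):
            m = bm.combine_risk_estimates([good, good, partial], 1, 832.0)
        assert m.n_rep == 2
        assert m.n_excluded == 1

    def test_too_few_retained_errors(self, scenario):
        good = constant_risk_model(scenario.mixture, [0.1, 0.05, 0.01, 0.02])
        coeffs = good.coeffs.copy()
        coeffs[0] = np.nan
        partial = bm.RiskModel(scenario.mixture, coeffs, degree=4)
        with pytest.raises(ValueError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bm.combine_risk_estimates([good, partial, partial], 1, 832.0)


class TestOverlapConstant:
    def test_single_sample_returns_c0(self):
        assert bm.overlap_constant(4.0, 0.7, 1) == pytest.approx(4.0)

    def test_small_phi_limit(self):
        assert bm.overlap_constant(4.0, 1e-9, 25) == pytest.approx(4.0, rel=1e-6)
        assert bm.overlap_constant(4.0, 0.0, 25) == 4.0

    def test_reference_population_value(self):
        # independent direct evaluation of the formula at the reported
        # heavy-smoking-population design: c0=4, phi=.2465, 25 samples
        phi, n_rep = 0.2465, 25
        direct = 4.0 * phi * n_rep / (1.0 - (1.0 - phi) ** n_rep)
        got = bm.overlap_constant(4.0, 0.2465, 25)
        assert got == pytest.approx(direct, rel=1e-12)
        assert got == pytest.approx(24.67, abs=0.01)

    def test_invalid_phi_rejected(self):
        for phi in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                bm.overlap_constant(4.0, phi, 25)

    @pytest.mark.parametrize("n_rep", [2, 5, 25])
    def test_nondecreasing_in_phi(self, n_rep):
        grid = np.linspace(0.001, 0.999, 200)
        vals = [bm.overlap_constant(4.0, p, n_rep) for p in grid]
        assert np.all(np.diff(vals) >= 0)


class TestIntervals:
    def test_ci_theta_with_bias(self):
        # thetas with mean -3 and sample sd exactly 0.5
        t = -3.0 + 0.5 * _unit_sd_vector(25)
        m = meta_of(t, bias=0.1)
        iv = bm.ci_theta(m, c=4.0, use_bias=True)
        assert (iv.lower, iv.upper) == (pytest.approx(-3.5), pytest.approx(-2.5))

    def test_ci_theta_without_bias(self):
        t = -3.0 + 0.5 * _unit_sd_vector(25)
        iv = bm.ci_theta(meta_of(t, bias=0.1), c=4.0, use_bias=False)
        assert (iv.lower, iv.upper) == (pytest.approx(-3.4), pytest.approx(-2.6))

    def test_degenerate_interval_flagged(self):
        iv = bm.ci_theta(meta_of([-3.0] * 5, bias=0.0), c=4.0)
        assert iv.degenerate
        assert iv.lower == iv.upper == -3.0

    def test_risk_interval_inverse_logit(self):
        t = -3.0 + 0.5 * _unit_sd_vector(25)
        iv = bm.risk_interval(meta_of(t, bias=0.1), c=4.0)
        assert iv.lower == pytest.approx(expit(-3.5), rel=1e-9)
        assert iv.upper == pytest.approx(expit(-2.5), rel=1e-9)
        assert iv.lower == pytest.approx(0.0293, abs=2e-4)
        assert iv.upper == pytest.approx(0.0759, abs=2e-4)

    def test_symmetric_logit_interval_symmetric_probability(self):
        t = 0.0 + 1.0 * _unit_sd_vector(16)
        iv = bm.risk_interval(meta_of(t), c=2.0)
        assert iv.lower + iv.upper == pytest.approx(1.0)

    def test_bias_interval_nests_plain_interval(self):
        t = -2.0 + 0.8 * _unit_sd_vector(10)
        m = meta_of(t, bias=0.3)
        with_b = bm.ci_theta(m, 3.0, use_bias=True)
        without = bm.ci_theta(m, 3.0, use_bias=False)
        assert with_b.lower <= without.lower
        assert with_b.upper >= without.upper

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mean=st.floats(-6, 2),
        sd=st.floats(0.01, 3),
        bias=st.floats(0, 1),
        c=st.floats(0.5, 10),
    )
    def test_monotone_map_property(self, mean, sd, bias, c):
        t = mean + sd * _unit_sd_vector(9)
        m = meta_of(t, bias=bias)
        li = bm.ci_theta(m, c)
        pi = bm.risk_interval(m, c)
        assert pi.lower <= pi.point <= pi.upper
        assert pi.lower == pytest.approx(expit(li.lower), rel=1e-9)
        assert pi.upper == pytest.approx(expit(li.upper), rel=1e-9)
        assert 0 < pi.lower and pi.upper < 1


class TestOddsRatios:
    def test_same_component_is_unity(self, scenario):
        fits = [constant_risk_model(scenario.mixture, [0.1, 0.05, 0.01, 0.02])] * 4
        iv, m = bm.odds_ratio_within(fits, 2, 2, 3000.0, c=4.0)
        assert iv.point == pytest.approx(1.0)
        assert m.s_theta == 0.0

    def test_reciprocity_exact(self, scenario):
        rng = np.random.default_rng(0)
        fits = [
            constant_risk_model(scenario.mixture, rng.uniform(0.01, 0.3, 4))
            for _ in range(6)
        ]
        a, _ = bm.odds_ratio_within(fits, 2, 4, 3000.0, c=4.0)
        b, _ = bm.odds_ratio_within(fits, 4, 2, 3000.0, c=4.0)
        assert a.point * b.point == pytest.approx(1.0, rel=1e-12)

    def test_constant_logit_difference(self, scenario):
        fits = [
            constant_risk_model(
                scenario.mixture, expit(np.array([-3.0, -4.0, -5.0, -5.0]))
            )
        ] * 3
        iv, _ = bm.odds_ratio_within(fits, 1, 2, 832.0, c=4.0)
        assert iv.point == pytest.approx(np.e, rel=1e-9)

    def test_between_populations_identical_gives_unity(self):
        t = -3.0 + 0.4 * _unit_sd_vector(25)
        m = meta_of(t, bias=0.1)
        iv = bm.odds_ratio_between(m, m, c=4.0)
        assert iv.point == pytest.approx(1.0)

    def test_between_populations_arithmetic(self):
        m1 = meta_of(-3.0 + 0.5 * _unit_sd_vector(25), bias=0.1)
        m2 = meta_of(-3.5 + 0.5 * _unit_sd_vector(25), bias=0.1)
        iv = bm.odds_ratio_between(m1, m2, c=4.0)
        half = 0.2 + 4.0 * np.sqrt(0.25 / 25 + 0.25 / 25)
        assert half == pytest.approx(0.2 + 4 * np.sqrt(0.02))
        assert iv.point == pytest.approx(np.exp(0.5))
        assert iv.lower == pytest.approx(np.exp(0.5 - half), rel=1e-9)
        assert iv.upper == pytest.approx(np.exp(0.5 + half), rel=1e-9)

    def test_mismatched_targets_rejected(self):
        m1 = meta_of(_unit_sd_vector(5), j=2, x0=3000.0)
        m2 = meta_of(_unit_sd_vector(5), j=3, x0=3000.0)
        with pytest.raises(ValueError):
            bm.odds_ratio_between(m1, m2, c=4.0)

    def test_degenerate_between_interval(self):
        m1 = meta_of([-3.0], j=2, x0=3000.0)
        m2 = meta_of([-3.5], j=2, x0=3000.0)
        iv = bm.odds_ratio_between(m1, m2, c=4.0)
        assert iv.degenerate
        assert iv.point == pytest.approx(np.exp(0.5))


class TestBiasAdjustment:
    def test_nonnegative_reproducible_and_order_invariant(self):
        mix = mixture_1()
        true_risk = constant_risk_model(mix, [0.05])
        targets = [RiskTarget(1, 2800.0), RiskTarget(1, 3000.0)]
        kwargs = dict(n=3000, n_sim=2, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = bm.bias_adjustment(mix, true_risk, targets, **kwargs)
            b2 = bm.bias_adjustment(mix, true_risk, list(reversed(targets)), **kwargs)
        for t in targets:
            assert b1[t] >= 0
            assert b1[t] == pytest.approx(b2[t], rel=1e-12)


class TestCovariateComponentProbability:
    def test_constant_risk_integrates_to_itself(self):
        model = constant_risk_model(mixture_1(), [0.37])
        assert bm.covariate_component_probability(model, 1) == pytest.approx(
            0.37, rel=1e-8
        )

    def test_linear_logit_matches_monte_carlo(self):
        mix = mixture_1()
        coeffs = np.array([[-1.0, 0.8, 0.0, 0.0, 0.0]])
        model = bm.RiskModel(mix, coeffs, degree=4)
        got = bm.covariate_component_probability(model, 1)
        rng = np.random.default_rng(99)
        draws = expit(-1.0 + 0.8 * rng.standard_normal(1_000_000))
        mc, se = draws.mean(), draws.std() / 1000.0
        assert abs(got - mc) < 3 * se

    def test_steep_polynomial_matches_monte_carlo(self):
        mix = mixture_1()
        coeffs = np.array([[-2.0, 6.0, 0.0, -1.5, 0.0]])
        model = bm.RiskModel(mix, coeffs, degree=4)
        got = bm.covariate_component_probability(model, 1)
        rng = np.random.default_rng(100)
        z = rng.standard_normal(1_000_000)
        draws = expit(-2.0 + 6.0 * z - 1.5 * z**3)
        mc, se = draws.mean(), draws.std() / 1000.0
        assert abs(got - mc) < 3 * se


class TestConfidenceBounds:
    def test_bounds_never_cross_point_curve(self, scenario):
        rng = np.random.default_rng(1)
        fits = [
            constant_risk_model(scenario.mixture, rng.uniform(0.005, 0.2, 4))
            for _ in range(8)
        ]
        grid = np.linspace(2800, 3500, 15)
        bounds = bm.confidence_bounds(fits, 3, grid, c=4.0, bias=0.05)
        assert (bounds["lower"] <= bounds["risk"]).all()
        assert (bounds["risk"] <= bounds["upper"]).all()

    def test_identical_fits_collapse_to_bias_band(self, scenario):
        fits = [constant_risk_model(scenario.mixture, [0.1, 0.05, 0.01, 0.02])] * 5
        grid = [3000.0, 3170.0]
        bounds = bm.confidence_bounds(fits, 3, grid, c=4.0, bias=0.2)
        for _, row in bounds.iterrows():
            assert row["lower"] == pytest.approx(expit(logit(0.01) - 0.2), rel=1e-9)
            assert row["upper"] == pytest.approx(expit(logit(0.01) + 0.2), rel=1e-9)


def _unit_sd_vector(n: int) -> np.ndarray:
    """Deterministic zero-mean vector with sample sd exactly 1."""
    v = np.arange(n, dtype=float)
    v -= v.mean()
    return v / v.std(ddof=1)
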