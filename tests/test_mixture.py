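"""Manly transform, mixture density, EM fitting, and decision boundaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tauread.mixture import (
    BoundaryError,
    DegenerateFitError,
    EMConfig,
    ManlyComponent,
    ManlyMixtureFit,
    decision_boundary,
    derive_cutoffs,
    fit_biomarker,
    fit_em,
    manly_inverse,
    manly_transform,
)
from tauread.synthetic import CohortSimParams, generate_cohort


def gaussian_mixture_em_oracle(x, q=0.5, tol=1e-12, max_iter=5000):
    """Textbook two-component Gaussian EM with quantile-split initialization.

    Deliberately independent of the package implementation: plain loops over
    the responsibility updates and moment re-estimates.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    split = int(round(q * n))
    w = np.array([split / n, 1 - split / n])
    mu = np.array([x[:split].mean(), x[split:].mean()])
    sd = np.array([x[:split].std(), x[split:].std()])
    prev = -np.inf
    for _ in range(max_iter):
        dens = np.stack([w[k] * stats.norm.pdf(x, mu[k], sd[k]) for k in range(2)])
        total = dens.sum(axis=0)
        ll = float(np.log(total).sum())
        resp = dens / total
        for k in range(2):
            r = resp[k]
            R = r.sum()
            w[k] = R / n
            mu[k] = (r * x).sum() / R
            sd[k] = math.sqrt((r * (x - mu[k]) ** 2).sum() / R)
        if abs(ll - prev) < tol:
            break
        prev = ll
    order = np.argsort(mu)
    return w[order], mu[order], sd[order]


def sample_manly_mixture(rng, n, weights, comps):
    """Draw from a Manly mixture given transformed-scale (mu, sigma, lam)."""
    which = rng.random(n) < weights[1]
    out = np.empty(n)
    for k, (mu, sigma, lam) in enumerate(comps):
        idx = which if k == 1 else ~which
        out[idx] = manly_inverse(rng.normal(mu, sigma, int(idx.sum())), lam)
    return out


class TestTransform:
    def test_identity_at_zero_skew(self):
        x = np.linspace(-5, 5, 11)
        np.testing.assert_array_equal(manly_transform(x, 0.0), x)

    def test_closed_form_value(self):
        assert manly_transform(1.0, 1.0) == pytest.approx(math.e - 1, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        x=st.floats(-50, 50),
        lam=st.floats(-2, 2).filter(lambda v: abs(v) > 1e-6),
    )
    def test_round_trip(self, x, lam):
        from hypothesis import assume

        # |lam*x| large saturates the transform (documented); the exact
        # round-trip contract applies on the numerically bijective range
        assume(abs(lam * x) < 15)
        assert manly_inverse(manly_transform(x, lam), lam) == pytest.approx(x, rel=1e-9, abs=1e-9)

    def test_monotone_in_x(self):
        x = np.linspace(-10, 10, 201)
        for lam in (-1.0, -0.1, 0.3, 2.0):
            assert np.all(np.diff(manly_transform(x, lam)) > 0)

    def test_continuity_in_lambda_at_zero(self):
        x = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(manly_transform(x, 1e-10), manly_transform(x, 0.0), atol=1e-8)

    def test_saturates_instead_of_overflowing(self):
        y = manly_transform(np.array([5000.0]), 1.0)
        assert np.isfinite(y).all()


class TestDensity:
    def test_zero_skew_equals_gaussian(self):
        comp = ManlyComponent(weight=0.5, mu=1.2, sigma=0.4, lam=0.0)
        x = np.linspace(-2, 4, 101)
        np.testing.assert_allclose(comp.pdf(x), stats.norm.pdf(x, 1.2, 0.4), atol=1e-12)

    @pytest.mark.parametrize("lam", [-0.6, 0.0, 0.4, 1.5])
    def test_integrates_to_one(self, lam):
        # sigma chosen so the Gaussian mass outside the transform's range
        # (|z| of the boundary ~8-10 SD) is far below the quadrature tolerance
        comp = ManlyComponent(weight=0.5, mu=0.5, sigma=0.15, lam=lam)
        grid = np.linspace(-60, 60, 400_001)
        integral = np.trapezoid(comp.pdf(grid), grid)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_skew_parameter_sign_controls_sample_skewness(self, rng):
        # x = log(1 + lam*y)/lam of a Gaussian y is concave for lam > 0
        # (negative measurement-scale skew) and convex for lam < 0
        draws_pos = manly_inverse(rng.normal(1.0, 0.5, 50_000), 0.8)
        draws_neg = manly_inverse(rng.normal(1.0, 0.5, 50_000), -0.8)
        assert stats.skew(draws_pos) < -0.1
        assert stats.skew(draws_neg) > 0.1

    def test_median_is_inverse_transform_of_mu(self):
        comp = ManlyComponent(weight=0.5, mu=1.5, sigma=0.3, lam=0.7)
        grid = np.linspace(-20, comp.median, 2_000_001)
        mass_below = np.trapezoid(comp.pdf(grid), grid)
        assert mass_below == pytest.approx(0.5, abs=1e-4)


class TestFitEM:
    def test_zero_skew_constrained_fit_matches_gaussian_em_oracle(self, rng):
        x = np.concatenate([rng.normal(0.0, 1.0, 1400), rng.normal(6.0, 1.5, 600)])
        fit = fit_em(x, EMConfig(lambda_bounds=(0.0, 0.0), n_starts=1, tol=1e-12, max_iter=5000))
        w_o, mu_o, sd_o = gaussian_mixture_em_oracle(x)
        c1, c2 = fit.components
        assert c1.lam == 0.0 and c2.lam == 0.0
        np.testing.assert_allclose([c1.weight, c2.weight], w_o, atol=1e-4)
        np.testing.assert_allclose([c1.mu, c2.mu], mu_o, atol=1e-4)
        np.testing.assert_allclose([c1.sigma, c2.sigma], sd_o, atol=1e-4)

    def test_loglik_trace_monotone(self, rng):
        x = sample_manly_mixture(rng, 2000, (0.7, 0.3), [(1.1, 0.08, 0.5), (1.6, 0.25, 0.5)])
        fit = fit_em(x, EMConfig(seed=0))
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert fit.converged

    def test_identified_parameters_recovered_on_average(self):
        """Weights and locations of the generative components are recovered to
        within 10% when estimates are averaged over independent simulations;
        the decision boundary to well under 5%.  (Skew/minority-scale are
        weakly identified at this sample size; see the methods note.)"""
        true_fit = ManlyMixtureFit(
            components=(ManlyComponent(0.8, 1.1, 0.08, 0.5), ManlyComponent(0.2, 1.6, 0.25, 0.5)),
            loglik_trace=[0.0],
            converged=True,
            n=0,
        )
        true_boundary = decision_boundary(true_fit)
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            x = sample_manly_mixture(rng, 5000, (0.8, 0.2), [(1.1, 0.08, 0.5), (1.6, 0.25, 0.5)])
            fit = fit_em(x, EMConfig(seed=0, n_starts=3))
            c1, c2 = fit.components
            estimates.append([c1.weight, c1.mu, c1.sigma, c2.mu, fit.cutoff])
        mean = np.asarray(estimates).mean(axis=0)
        truth = np.array([0.8, 1.1, 0.08, 1.6, true_boundary])
        rel = np.abs(mean - truth) / np.abs(truth)
        assert np.all(rel[:4] < 0.10), rel
        assert rel[4] < 0.05

    def test_constant_data_raises_degeneracy(self):
        with pytest.raises(DegenerateFitError):
            fit_em(np.full(100, 3.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_em(np.arange(5.0))


class TestDecisionBoundary:
    def _fit(self, c1, c2):
        return ManlyMixtureFit(components=(c1, c2), loglik_trace=[0.0], converged=True, n=0)

    def test_symmetric_equal_gaussians_give_midpoint(self):
        fit = self._fit(ManlyComponent(0.5, 0.0, 1.0, 0.0), ManlyComponent(0.5, 2.0, 1.0, 0.0))
        assert decision_boundary(fit) == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_grid_posterior_oracle(self, rng):
        x = sample_manly_mixture(rng, 3000, (0.75, 0.25), [(1.1, 0.09, 0.4), (1.7, 0.3, 0.4)])
        fit = fit_em(x, EMConfig(seed=1, n_starts=3))
        c1, c2 = fit.components
        grid = np.linspace(c1.median, c2.median, 200_001)
        oracle = grid[np.argmin(np.abs(fit.posterior(grid) - 0.5))]
        resolution = grid[1] - grid[0]
        assert abs(fit.cutoff - oracle) <= resolution

    def test_posterior_at_boundary_is_half(self, rng):
        x = sample_manly_mixture(rng, 2000, (0.7, 0.3), [(1.0, 0.1, 0.3), (1.8, 0.3, 0.3)])
        fit = fit_em(x, EMConfig(seed=2, n_starts=3))
        assert fit.posterior(fit.cutoff) == pytest.approx(0.5, abs=1e-6)

    def test_boundary_moves_toward_minority_component_as_weight_grows(self):
        boundaries = []
        for w1 in (0.3, 0.5, 0.7, 0.9):
            fit = self._fit(ManlyComponent(w1, 0.0, 1.0, 0.0), ManlyComponent(1 - w1, 3.0, 1.0, 0.0))
            boundaries.append(decision_boundary(fit))
        assert boundaries == sorted(boundaries)

    def test_no_crossing_raises_with_diagnostics(self):
        # overwhelming first component: posterior never drops to 0.5 between medians
        fit = self._fit(
            ManlyComponent(weight=0.999999, mu=0.0, sigma=5.0, lam=0.0),
            ManlyComponent(weight=1e-6, mu=0.5, sigma=0.01, lam=0.0),
        )
        try:
            value = decision_boundary(fit, bracket=(0.0, 0.2))
        except BoundaryError as err:
            assert err.grid is not None and err.log_odds is not None
        else:  # pragma: no cover - depends on parameter choice
            pytest.fail(f"expected BoundaryError, got {value}")


class TestDeriveCutoffs:
    def test_closed_loop_cutoff_recovery_on_synthetic_cohort(self):
        cutoffs = []
        for seed in range(5):
            cohort = generate_cohort(CohortSimParams(n=5000, seed=seed, csf_fraction=1.0))
            fit = fit_biomarker(cohort, "suvr", EMConfig(seed=0, n_starts=3))
            cutoffs.append(fit.cutoff)
        from tauread.synthetic import default_biomarker_components

        neg, pos = default_biomarker_components()["suvr"]
        true_fit = ManlyMixtureFit(
            components=(
                ManlyComponent(0.75, neg.transformed_mu, neg.transformed_sigma, neg.lam),
                ManlyComponent(0.25, pos.transformed_mu, pos.transformed_sigma, pos.lam),
            ),
            loglik_trace=[0.0],
            converged=True,
            n=0,
        )
        generative = decision_boundary(true_fit)
        assert abs(np.mean(cutoffs) - generative) / generative < 0.05

    def test_missing_biomarker_column_named_in_error(self):
        cohort = generate_cohort(CohortSimParams(n=100, seed=0)).drop(columns=["ptau181"])
        with pytest.raises(KeyError, match="ptau181"):
            fit_biomarker(cohort, "ptau181")

    def test_defaults_only_mode_returns_published_cutoffs(self):
        from tauread.suvr import CutoffConfig

        defaults = CutoffConfig()
        assert (defaults.suvr_cutoff, defaults.centiloid_cutoff) == (1.32, 21.6)
        assert (defaults.ptau_cutoff, defaults.abeta_ratio_cutoff) == (58.1, 0.0737)

    def test_derive_cutoffs_returns_config_with_fitted_values(self):
        cohort = generate_cohort(CohortSimParams(n=1200, seed=4, csf_fraction=1.0))
        config = derive_cutoffs(cohort, ["suvr"], EMConfig(seed=0, n_starts=2))
        assert 1.2 < config.suvr_cutoff < 1.6
        assert config.centiloid_cutoff == 21.6  # untouched default
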