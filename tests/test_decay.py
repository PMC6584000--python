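import arviz as az
import numpy as np
import pytest

from plume_ed.decay import (
    DecayModelSpec,
    apply_transform,
    fit_decay,
    posterior_predict_mean,
    _split_rhat,
)
from plume_ed.synthetic import simulate_mixed_response, simulate_sites


def _conjugate_posterior(X, y, sigma, prior_sd):
    """Closed-form normal posterior for known-variance linear regression."""
    prec = X.T @ X / sigma**2 + np.eye(X.shape[1]) / prior_sd**2
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ y) / sigma**2
    return mean, cov


class TestApplyTransform:
    def test_passthrough_and_named_scales(self):
        np.testing.assert_allclose(apply_transform([4.0], "sqrt"), [2.0])
        np.testing.assert_allclose(apply_transform([100.0], "log10"), [2.0])
        np.testing.assert_allclose(apply_transform([0.5], "logit"), [0.0])

    def test_logit_applies_empirical_correction_with_counts(self):
        out = apply_transform([0.0], "logit", correction=0.5, counts=10)
        expected = np.log((0.5 / 11) / (1 - 0.5 / 11))
        assert out[0] == pytest.approx(expected)

    def test_out_of_domain_after_correction_raises(self):
        with pytest.raises(ValueError):
            apply_transform([-0.2], "logit")


class TestGibbsSampler:
    def test_degenerate_noise_recovery(self):
        """Noise-free data: posterior concentrates on the generating line."""
        d = np.repeat(np.logspace(np.log10(0.19), np.log10(34.8), 17), 3)
        y = 2.0 - 1.0 * np.log10(d)
        spec = DecayModelSpec.test_profile(
            include_site=False, include_fortnight=False, seed=7
        )
        draws = fit_decay(y, d, spec=spec)
        assert draws.stacked("beta0").mean() == pytest.approx(2.0, abs=1e-2)
        assert draws.stacked("beta1").mean() == pytest.approx(-1.0, abs=1e-2)
        assert draws.stacked("sigma_resid").mean() < 0.05

    def test_matches_conjugate_closed_form(self):
        """Known variance, no random effects: Gibbs draws must reproduce the
        analytic normal posterior."""
        rng = np.random.default_rng(21)
        n = 150
        x = rng.uniform(-0.72, 1.54, size=n)
        sigma = 0.25
        y = 1.2 - 0.7 * x + rng.normal(0, sigma, size=n)
        X = np.column_stack([np.ones(n), x])
        mean, cov = _conjugate_posterior(X, y, sigma, prior_sd=100.0)
        spec = DecayModelSpec.test_profile(
            include_site=False, include_fortnight=False, known_resid_sd=sigma, seed=8
        )
        draws = fit_decay(y, 10.0**x, spec=spec)
        b = np.column_stack([draws.stacked("beta0"), draws.stacked("beta1")])
        # means to a fraction of the posterior SD; SDs to Monte-Carlo error
        np.testing.assert_allclose(b.mean(axis=0), mean, atol=0.1 * np.sqrt(np.diag(cov)).max())
        np.testing.assert_allclose(b.std(axis=0, ddof=1), np.sqrt(np.diag(cov)), rtol=0.05)

    def test_mixed_model_covers_truth_single_replicate(self):
        d = simulate_sites(17, 0.19, 34.8)["distance_km"].to_numpy()
        panel = simulate_mixed_response(
            d, 38, beta0=0.5, beta1=-0.8,
            sd_site=0.3, sd_fortnight=0.2, sd_resid=0.2, seed=4,
        )
        spec = DecayModelSpec.test_profile(seed=5)
        draws = fit_decay(
            panel["y"], panel["distance_km"], panel["site_id"], panel["fortnight"], spec
        )
        summary = draws.summary().set_index("parameter")
        for name, truth in [("beta1", -0.8), ("sigma_resid", 0.2)]:
            lo, hi = summary.loc[name, ["q2.5", "q97.5"]]
            assert lo < truth < hi
        assert all(r < 1.05 for r in draws.rhat.values())

    def test_row_permutation_leaves_posterior_unchanged(self):
        d = simulate_sites(8, 0.19, 34.8)["distance_km"].to_numpy()
        panel = simulate_mixed_response(
            d, 10, beta0=0.0, beta1=-0.6,
            sd_site=0.2, sd_fortnight=0.1, sd_resid=0.2, seed=11,
        )
        spec = DecayModelSpec.test_profile(seed=12)
        base = fit_decay(
            panel["y"], panel["distance_km"], panel["site_id"], panel["fortnight"], spec
        )
        shuffled = panel.sample(frac=1.0, random_state=3).reset_index(drop=True)
        perm = fit_decay(
            shuffled["y"], shuffled["distance_km"], shuffled["site_id"],
            shuffled["fortnight"], spec,
        )
        # equality up to MCMC noise: compare within a few Monte-Carlo SEs
        for name in ("beta0", "beta1", "sigma_resid"):
            a, b = base.stacked(name), perm.stacked(name)
            tol = 4 * a.std(ddof=1) / np.sqrt(200)  # conservative ESS guess
            assert abs(a.mean() - b.mean()) < tol

    def test_slope_sign_recovered_with_strong_gradient(self):
        d = simulate_sites(12, 0.19, 34.8)["distance_km"].to_numpy()
        panel = simulate_mixed_response(
            d, 12, beta0=0.0, beta1=-1.5,
            sd_site=0.1, sd_fortnight=0.1, sd_resid=0.2, seed=13,
        )
        spec = DecayModelSpec.test_profile(seed=14)
        draws = fit_decay(
            panel["y"], panel["distance_km"], panel["site_id"], panel["fortnight"], spec
        )
        assert (draws.stacked("beta1") < 0).mean() > 0.99

    def test_singular_design_raises_collinearity_error(self):
        y = np.array([1.0, 2.0, 1.5, 1.7])
        with pytest.raises(ValueError, match="collinear"):
            fit_decay(
                y, np.full(4, 2.0),
                spec=DecayModelSpec.test_profile(
                    include_site=False, include_fortnight=False
                ),
            )

    def test_site_and_fortnight_preconditions(self, quick_spec):
        y = np.arange(6.0)
        d = np.array([1.0, 1.0, 2.0, 2.0, 4.0, 4.0])
        sites = ["a", "a", "b", "b", "c", "c"]
        with pytest.raises(ValueError, match="fortnight"):
            fit_decay(y, d, site_id=sites, fortnight=[1] * 6, spec=quick_spec)
        with pytest.raises(ValueError, match="sites"):
            fit_decay(
                y, d, site_id=["a"] * 6, fortnight=[1, 2, 1, 2, 1, 2], spec=quick_spec
            )


def test_posterior_mean_matches_ols_under_flat_prior():
    """With a near-flat prior and no random effects the posterior mean of
    (beta0, beta1) must agree with the frequentist least-squares fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(31)
    n = 120
    x = rng.uniform(-0.72, 1.54, size=n)
    y = 0.8 - 1.1 * x + rng.normal(0, 0.3, size=n)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    spec = DecayModelSpec.test_profile(
        include_site=False, include_fortnight=False, seed=32
    )
    draws = fit_decay(y, 10.0**x, spec=spec)
    assert draws.stacked("beta0").mean() == pytest.approx(ols.params[0], abs=3e-3)
    assert draws.stacked("beta1").mean() == pytest.approx(ols.params[1], abs=3e-3)
    assert draws.stacked("sigma_resid").mean() == pytest.approx(
        np.sqrt(ols.scale), rel=0.05
    )


class TestDiagnostics:
    def test_split_rhat_agrees_with_arviz(self, rng):
        chains = rng.normal(size=(4, 400)) + rng.normal(size=(4, 1)) * 0.3
        ours = _split_rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains),
                               method="split")["x"].values)
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_constant_chain_is_converged(self):
        assert _split_rhat(np.full((3, 100), 0.3)) == 1.0

    def test_well_specified_fit_converges_below_threshold(self):
        d = simulate_sites(10, 0.19, 34.8)["distance_km"].to_numpy()
        panel = simulate_mixed_response(
            d, 12, beta0=0.0, beta1=-0.8,
            sd_site=0.3, sd_fortnight=0.2, sd_resid=0.2, seed=17,
        )
        spec = DecayModelSpec.test_profile(seed=18)
        draws = fit_decay(
            panel["y"], panel["distance_km"], panel["site_id"], panel["fortnight"], spec
        )
        assert max(draws.rhat.values()) < 1.05


class TestPosteriorPredict:
    def test_one_km_returns_intercept_draws(self):
        d = np.repeat([0.5, 2.0, 8.0], 4)
        y = 1.0 - 0.5 * np.log10(d)
        spec = DecayModelSpec.test_profile(
            include_site=False, include_fortnight=False, seed=2,
            n_burnin=100, n_iter=200,
        )
        draws = fit_decay(y, d, spec=spec)
        np.testing.assert_allclose(
            posterior_predict_mean(draws, 1.0), draws.stacked("beta0")
        )
        pred10 = posterior_predict_mean(draws, 10.0)
        np.testing.assert_allclose(
            pred10, draws.stacked("beta0") + draws.stacked("beta1")
        )

    def test_nonpositive_distance_rejected(self):
        d = np.repeat([0.5, 2.0, 8.0], 4)
        y = np.ones(12)
        spec = DecayModelSpec.test_profile(
            include_site=False, include_fortnight=False,
            n_burnin=50, n_iter=100,
        )
        draws = fit_decay(y + np.linspace(0, 0.1, 12), d, spec=spec)
        with pytest.raises(ValueError):
            posterior_predict_mean(draws, 0.0)


def test_spec_validation():
    with pytest.raises(ValueError):
        DecayModelSpec(n_chains=1)
    with pytest.raises(ValueError):
        DecayModelSpec(n_iter=0)
    with pytest.raises(ValueError):
        DecayModelSpec(transform="cube-root")
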