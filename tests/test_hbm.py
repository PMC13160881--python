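"""MCMC machinery: transforms, likelihood, Gibbs and MH kernels, chains."""

import numpy as np
import pytest
from scipy.stats import invwishart

from hbmfit.hbm import (
    BSPState,
    ChainConfig,
    ParameterTransform,
    adapt_proposals,
    gibbs_update_prior,
    init_chain,
    log_likelihood,
    mh_update_voxel,
    run_chain,
)
from hbmfit.lsq import fit_volume
from hbmfit.signal_models import dki_scheme, fexi_scheme, get_model


class TestTransform:
    def test_round_trip_identity(self, dki, rng):
        tr = ParameterTransform.for_model(dki)
        x = rng.uniform(dki.lb + 1e-3, dki.ub - 1e-3, size=(500, 2))
        np.testing.assert_allclose(tr.to_native(tr.to_unbounded(x)), x, atol=1e-12)

    def test_strictly_increasing(self, dki):
        tr = ParameterTransform.for_model(dki)
        u = np.linspace(-8, 8, 200)[:, None] * np.ones(2)
        x = tr.to_native(u)
        assert np.all(np.diff(x, axis=0) > 0)

    def test_native_values_always_inside_bounds(self, axr, rng):
        # |u| <= ~30 covers anything a chain can reach; beyond that the
        # sigmoid underflows and x rounds onto the bound itself
        tr = ParameterTransform.for_model(axr)
        u = rng.normal(0, 8, size=(1000, 3))
        x = tr.to_native(u)
        assert np.all(x > axr.lb) and np.all(x < axr.ub)

    def test_jacobian_matches_finite_differences(self, dki):
        tr = ParameterTransform.for_model(dki)
        u = np.array([0.3, -1.2])
        h = 1e-6
        for j in range(2):
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            fd = (tr.to_native(up)[j] - tr.to_native(um)[j]) / (2 * h)
            assert tr.dx_du(u)[j] == pytest.approx(fd, rel=1e-6)


class TestLogLikelihood:
    def test_maximised_at_truth_on_noise_free_data(self, dki):
        sch = dki_scheme()
        truth = np.array([0.9, 1.1])
        y = dki.predict(truth, sch)
        ll0 = log_likelihood(y, truth, sch, dki)
        for d in np.linspace(-0.2, 0.2, 9):
            if d == 0:
                continue
            assert log_likelihood(y, truth + [d, 0.0], sch, dki) < ll0
            assert log_likelihood(y, truth + [0.0, d], sch, dki) < ll0

    def test_doubling_residuals_shifts_by_half_n_log_four(self, dki, rng):
        sch = dki_scheme()
        theta = np.array([1.0, 0.8])
        y1 = dki.predict(theta, sch) + rng.normal(0, 0.05, 4)
        resid = y1 - dki.predict(theta, sch)
        y2 = dki.predict(theta, sch) + 2 * resid
        n = 4
        assert log_likelihood(y2, theta, sch, dki) == pytest.approx(
            log_likelihood(y1, theta, sch, dki) - 0.5 * n * np.log(4), rel=1e-12
        )

    def test_flat_likelihood_without_data(self, dki):
        assert log_likelihood(None, np.array([1.0, 1.0]), dki_scheme(), dki) == 0.0

    def test_exact_fit_guarded_by_floor(self, dki):
        sch = dki_scheme()
        theta = np.array([1.0, 0.8])
        y = dki.predict(theta, sch)
        assert np.isfinite(log_likelihood(y, theta, sch, dki))


class TestGibbs:
    def test_mu_long_run_average_matches_conditional_mean(self, rng):
        """Mean of mu draws at fixed theta = ROI sample mean (closed form)."""
        theta = rng.normal([0.5, -1.0], [0.3, 0.6], size=(40, 2))
        sigma = np.array([[0.09, 0.02], [0.02, 0.36]])
        draws = np.array(
            [gibbs_update_prior(theta, sigma, rng)[0] for _ in range(10_000)]
        )
        se = np.sqrt(np.diag(sigma) / len(theta) / len(draws))
        assert np.all(np.abs(draws.mean(0) - theta.mean(0)) < 4 * se)

    def test_sigma_concentrates_at_sample_covariance_for_large_roi(self, rng):
        """I_k -> inf: the inverse-Wishart conditional mean -> S / I_k."""
        cov = np.array([[0.25, 0.1], [0.1, 0.5]])
        theta = rng.multivariate_normal([0.0, 0.0], cov, size=20_000)
        sigmas = np.array(
            [gibbs_update_prior(theta, cov, rng)[1] for _ in range(200)]
        )
        emp = np.cov(theta.T, bias=True)
        np.testing.assert_allclose(sigmas.mean(0), emp, rtol=0.05)

    def test_sigma_draw_moments_match_scipy_invwishart(self, rng):
        """Given mu, the Sigma conditional is IW(nu0 + I, Psi0 + S)."""
        theta = rng.normal(size=(30, 2))
        sigma0 = np.eye(2)
        # freeze mu by drawing many times and conditioning manually
        mu = theta.mean(0)
        dev = theta - mu
        scale = 1e-6 * np.eye(2) + dev.T @ dev
        df = 3 + 30
        expected_mean = scale / (df - 2 - 1)
        draws = np.array([
            invwishart.rvs(df=df, scale=scale, random_state=rng) for _ in range(4000)
        ])
        np.testing.assert_allclose(draws.mean(0), expected_mean, rtol=0.1)

    def test_identical_voxels_floor_on_psi0(self, rng):
        theta = np.tile([0.2, 0.4], (2, 1))
        mu, sigma = gibbs_update_prior(theta, 1e-4 * np.eye(2), rng,
                                       psi0_scale=1e-6)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)
        assert np.all(np.diag(sigma) < 1e-4)

    def test_single_voxel_roi_rejected(self, rng):
        with pytest.raises(ValueError):
            gibbs_update_prior(np.ones((1, 2)), np.eye(2), rng)


class TestMH:
    def test_zero_width_always_accepts_and_keeps_chain_constant(self, dki, rng):
        sch = dki_scheme()
        theta = np.zeros((5, 2))
        y = np.tile(dki.predict(np.array([1.0, 1.0]), sch), (5, 1))
        new, acc = mh_update_voxel(
            theta, y, np.zeros(2), np.eye(2), np.zeros((5, 2)), rng, sch, dki
        )
        assert acc.all()
        np.testing.assert_array_equal(new, theta)

    def test_flat_likelihood_samples_the_prior(self, dki, rng):
        """With no data the native-space stationary law is N(mu, sigma)
        (truncation is negligible for a prior well inside the bounds)."""
        tr = ParameterTransform.for_model(dki)
        mu = np.array([1.0, 1.2])
        sigma = np.array([[0.0225, 0.006], [0.006, 0.04]])
        theta = np.tile(tr.to_unbounded(mu), (200, 1))
        widths = np.full((200, 2), 0.4)
        keep = []
        for s in range(1500):
            theta, _ = mh_update_voxel(
                theta, None, mu, sigma, widths, rng, dki_scheme(), dki
            )
            if s >= 500:
                keep.append(tr.to_native(theta))
        samples = np.concatenate(keep)           # ~2e5 correlated draws
        np.testing.assert_allclose(samples.mean(0), mu, atol=0.01)
        np.testing.assert_allclose(np.cov(samples.T), sigma, atol=0.005)

    def test_conjugate_gaussian_posterior_recovered(self, dki, rng):
        """Known-noise Gaussian likelihood + Gaussian prior on a directly
        observed parameter: the posterior is the closed-form Gaussian
        product (bound truncation negligible); the MH kernel must
        reproduce its mean within Monte-Carlo error."""
        sch = dki_scheme()
        tr = ParameterTransform.for_model(dki)
        tau = 0.05
        y_obs = 1.3
        mu_x, var_x = 1.0, 0.09           # prior on native D
        nchains = 400

        def loglik(theta_nat):
            return -0.5 * ((theta_nat[:, 0] - y_obs) / tau) ** 2

        sigma = np.diag([var_x, 1e4])     # K effectively unconstrained
        mu = np.array([mu_x, 1.5])
        theta = np.tile(tr.to_unbounded(mu), (nchains, 1))
        widths = np.full((nchains, 2), 0.3)
        keep = []
        for s in range(1000):
            theta, _ = mh_update_voxel(
                theta, None, mu, sigma, widths, rng, sch, dki, loglik_fn=loglik
            )
            if s >= 400:
                keep.append(tr.to_native(theta)[:, 0])
        samples = np.concatenate(keep)
        # closed form: precision-weighted mean and variance
        post_var = 1.0 / (1.0 / tau**2 + 1.0 / var_x)
        post_mean = post_var * (y_obs / tau**2 + mu_x / var_x)
        n_eff = nchains * 10  # conservative: strong autocorrelation within chains
        assert samples.mean() == pytest.approx(
            post_mean, abs=3 * np.sqrt(post_var / n_eff)
        )
        assert samples.std() == pytest.approx(np.sqrt(post_var), rel=0.1)


class TestAdaptation:
    def test_on_target_acceptance_leaves_widths_unchanged(self):
        w = np.full((10, 2), 0.5)
        out = adapt_proposals(np.full((10, 2), 25.0), 100, w)
        np.testing.assert_allclose(out, w)

    def test_zero_acceptance_shrinks_by_clip_floor(self):
        w = np.full((4, 2), 1.0)
        out = adapt_proposals(np.zeros((4, 2)), 100, w)
        np.testing.assert_allclose(out, 0.5 * w)

    def test_full_acceptance_clipped_at_doubling(self):
        w = np.full((4, 2), 1.0)
        out = adapt_proposals(np.full((4, 2), 100.0), 100, w)
        np.testing.assert_allclose(out, 2.0 * w)


class TestInitChain:
    def test_initialisation_deterministic_and_in_bounds(self, small_dki_phantom, dki):
        ph = small_dki_phantom
        lsq = fit_volume(ph.noisy, ph.labels, ph.scheme, dki)
        tr = ParameterTransform.for_model(dki)
        out1 = init_chain(lsq, ph.labels, dki, tr)
        out2 = init_chain(lsq, ph.labels, dki, tr)
        np.testing.assert_array_equal(out1[0], out2[0])
        native = tr.to_native(out1[0])
        assert np.all(native > dki.lb) and np.all(native < dki.ub)
        # native-space prior means start inside the bounds
        assert np.all(out1[2].mu > dki.lb) and np.all(out1[2].mu < dki.ub)

    def test_degenerate_identical_fits_get_floored_covariance(self, dki):
        sch = dki_scheme()
        y = dki.predict(np.array([0.9, 1.1]), sch)
        data = np.tile(y, (3, 3, 1))
        labels = np.ones((3, 3), dtype=int)
        lsq = fit_volume(data, labels, sch, dki)
        tr = ParameterTransform.for_model(dki)
        _theta, widths, bsp, _lab, _ids = init_chain(lsq, labels, dki, tr)
        assert np.all(np.linalg.eigvalsh(bsp.sigma[0]) > 0)
        assert np.all(widths > 0)


class TestRunChain:
    def test_noise_free_phantom_recovers_truth(self, small_dki_phantom, dki):
        ph = small_dki_phantom
        cfg = ChainConfig(n_steps=4000, seed=5)
        out = run_chain(ph.clean, ph.labels, ph.scheme, dki, cfg)
        mask = ph.labels > 0
        for name in dki.param_names:
            rel = np.abs(
                out.mean_maps[name][mask] - ph.truth_maps[name][mask]
            ) / ph.truth_maps[name][mask]
            assert np.median(rel) < 0.01

    def test_shrinkage_reduces_roi_variance_vs_lsq(self, small_dki_phantom, dki):
        ph = small_dki_phantom
        lsq = fit_volume(ph.noisy, ph.labels, ph.scheme, dki)
        out = run_chain(ph.noisy, ph.labels, ph.scheme, dki,
                        ChainConfig(n_steps=4000, seed=6), init=lsq)
        for k in (1, 2):
            sel = ph.labels == k
            for name in dki.param_names:
                assert np.var(out.mean_maps[name][sel]) <= np.var(
                    lsq.maps[name][sel]
                )

    def test_posterior_means_respect_bounds(self, small_fexi_phantom, axr):
        ph = small_fexi_phantom
        out = run_chain(ph.noisy, ph.labels, ph.scheme, axr,
                        ChainConfig(n_steps=2000, seed=3))
        mask = ph.labels > 0
        for j, name in enumerate(axr.param_names):
            v = out.mean_maps[name][mask]
            assert np.all(v > axr.lb[j]) and np.all(v < axr.ub[j])

    def test_bit_reproducible_under_fixed_seed(self, small_dki_phantom, dki):
        ph = small_dki_phantom
        lsq = fit_volume(ph.noisy, ph.labels, ph.scheme, dki)
        a = run_chain(ph.noisy, ph.labels, ph.scheme, dki,
                      ChainConfig(n_steps=800, seed=42), init=lsq)
        b = run_chain(ph.noisy, ph.labels, ph.scheme, dki,
                      ChainConfig(n_steps=800, seed=42), init=lsq)
        for name in dki.param_names:
            np.testing.assert_array_equal(a.mean_maps[name], b.mean_maps[name])
        assert not np.array_equal(
            a.mean_maps["K"],
            run_chain(ph.noisy, ph.labels, ph.scheme, dki,
                      ChainConfig(n_steps=800, seed=43), init=lsq).mean_maps["K"],
        )

    def test_acceptance_rates_land_in_band_after_adaptation(
        self, small_dki_phantom, dki
    ):
        ph = small_dki_phantom
        out = run_chain(ph.noisy, ph.labels, ph.scheme, dki,
                        ChainConfig(n_steps=6000, seed=8))
        rates = out.acceptance_map[ph.labels > 0]
        assert np.mean((rates > 0.1) & (rates < 0.5)) >= 0.9

    def test_single_global_prior_runs(self, small_dki_phantom, dki):
        ph = small_dki_phantom
        labels = (ph.labels > 0).astype(int)
        out = run_chain(ph.noisy, labels, ph.scheme, dki,
                        ChainConfig(n_steps=1000, seed=2))
        assert set(out.prior_summary["roi"]) == {1}

    def test_prior_summary_in_native_units(self, small_dki_phantom, dki):
        ph = small_dki_phantom
        out = run_chain(ph.noisy, ph.labels, ph.scheme, dki,
                        ChainConfig(n_steps=2000, seed=9))
        tab = out.prior_summary.set_index(["roi", "parameter"])
        # WM kurtosis prior mean should sit near the WM ground-truth mean
        assert 0.6 < tab.loc[(1, "K"), "prior_mean"] < 1.6
        assert 0.2 < tab.loc[(2, "K"), "prior_mean"] < 1.1
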