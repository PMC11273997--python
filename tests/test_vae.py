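import numpy as np
import pytest

from latentlink import metrics, simulate, vae


class TestKLDivergence:
    def test_standard_posterior_has_zero_kl(self):
        assert vae.kl_divergence(np.zeros((1, 3)), np.zeros((1, 3)))[0] == 0.0

    def test_closed_form_matches_monte_carlo(self, rng):
        """Analytic KL for diagonal Gaussians vs. a sampling estimate."""
        mu = rng.normal(size=(5, 2))
        logvar = rng.normal(scale=0.5, size=(5, 2))
        analytic = vae.kl_divergence(mu, logvar)
        n_mc = 200_000
        for i in range(5):
            s = np.exp(0.5 * logvar[i])
            z = mu[i] + s * rng.standard_normal((n_mc, 2))
            log_q = np.sum(
                -0.5 * np.log(2 * np.pi) - 0.5 * logvar[i]
                - 0.5 * ((z - mu[i]) / s) ** 2, axis=1
            )
            log_p = np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * z**2, axis=1)
            mc = np.mean(log_q - log_p)
            assert analytic[i] == pytest.approx(mc, abs=4 * np.std(log_q - log_p) / np.sqrt(n_mc))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Hand-written gradients vs. central differences on a tiny model."""
        cfg = vae.VAEConfig(n_items=4, hidden_units=3, latent_dim=2, seed=0)
        params = vae._init_params(cfg, rng)
        x = rng.normal(size=(6, 4))
        eps = rng.standard_normal((6, 2))
        _, grads = vae._loss_and_grads(params, x, eps, kl_weight=1.0)
        h = 1e-6
        for name in ("enc_w1", "enc_wv", "dec_w2", "enc_bm", "dec_b1"):
            w = params[name]
            idx = tuple(0 for _ in w.shape)
            w[idx] += h
            lp, _ = vae._loss_and_grads(params, x, eps, 1.0)
            w[idx] -= 2 * h
            lm, _ = vae._loss_and_grads(params, x, eps, 1.0)
            w[idx] += h
            numeric = (lp - lm) / (2 * h)
            assert grads[name][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_deterministic_under_seed(self, linear_dataset):
        cfg = vae.VAEConfig(epochs=5, k_folds=2, seed=9)
        a = vae.train(linear_dataset.responses[:300], cfg)
        b = vae.train(linear_dataset.responses[:300], cfg)
        assert np.array_equal(a.latent_mean, b.latent_mean)
        assert np.array_equal(a.sampled_z, b.sampled_z)
        assert a.selected_fold == b.selected_fold

    def test_loss_trend_non_increasing(self, trained_linear_vae):
        curve = trained_linear_vae.train_curve
        k = 10
        smooth = np.convolve(curve, np.ones(k) / k, mode="valid")
        assert smooth[-1] <= smooth[0]
        # no sustained increase anywhere
        assert np.all(np.diff(smooth) < 0.05 * smooth[0])

    def test_fold_selection_takes_minimum(self, trained_linear_vae):
        assert (
            trained_linear_vae.selected_fold
            == int(np.argmin(trained_linear_vae.fold_losses))
        )

    def test_latent_regularized_towards_standard_normal(self, trained_linear_vae_full):
        mu = trained_linear_vae_full.latent_mean.ravel()
        assert abs(mu.mean()) < 0.15
        assert mu.var() == pytest.approx(1.0, abs=0.25)

    def test_latent_density_close_to_gaussian(self, trained_linear_vae_full):
        from scipy import stats

        mu = trained_linear_vae_full.latent_mean.ravel()
        assert abs(stats.skew(mu)) < 0.3
        assert abs(stats.kurtosis(mu)) < 0.5

    def test_nonfinite_input_rejected(self):
        x = np.zeros((50, 8))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            vae.train(x, vae.VAEConfig(epochs=1, k_folds=2))

    def test_constant_input_degenerate_optimum(self):
        # Adam moves each weight by roughly the learning rate per step, so
        # give the optimizer enough steps to park the decoder bias
        x = np.full((120, 8), 0.5)
        sol = vae.train(
            x, vae.VAEConfig(epochs=300, k_folds=2, batch_size=16, seed=1)
        )
        recon_err = np.mean((vae.reconstruct(sol, "mean") - x) ** 2)
        kl = vae.kl_divergence(sol.latent_mean, sol.latent_logvar).mean()
        assert recon_err < 0.05
        assert kl < 0.05


class TestEncodeAndReconstruct:
    def test_encoding_deterministic(self, trained_linear_vae, linear_dataset):
        a = vae.encode_scores(
            trained_linear_vae, linear_dataset.responses, linear_dataset.true_scores
        )
        b = vae.encode_scores(
            trained_linear_vae, linear_dataset.responses, linear_dataset.true_scores
        )
        assert np.array_equal(a, b)

    def test_alignment_fixes_sign(self, trained_linear_vae, linear_dataset):
        sc = vae.encode_scores(
            trained_linear_vae, linear_dataset.responses, linear_dataset.true_scores
        )
        corr = np.corrcoef(sc.ravel(), linear_dataset.true_scores.ravel())[0, 1]
        assert corr > 0.9

    def test_dimension_mismatch_rejected(self, trained_linear_vae):
        with pytest.raises(ValueError, match="items"):
            vae.encode_scores(trained_linear_vae, np.zeros((10, 5)))

    def test_sampled_redraw_reproducible(self, trained_linear_vae, linear_dataset):
        sol = trained_linear_vae
        eps = np.random.default_rng(sol.sample_seed).standard_normal(
            sol.latent_mean.shape
        )
        z = sol.latent_mean + np.exp(0.5 * sol.latent_logvar) * eps
        assert np.array_equal(z, sol.sampled_z)

    def test_sampled_more_dispersed_than_mean(self, trained_linear_vae):
        vs = np.var(vae.reconstruct(trained_linear_vae, "sampled"), axis=0)
        vm = np.var(vae.reconstruct(trained_linear_vae, "mean"), axis=0)
        assert np.all(vs >= vm - 1e-9)

    def test_recon_slope_tracks_latent(self, trained_linear_vae_full, linear_dataset):
        # on linear data the decoder is essentially affine in the latent
        sc = vae.encode_scores(
            trained_linear_vae_full, linear_dataset.responses, linear_dataset.true_scores
        )
        rec = vae.reconstruct(trained_linear_vae_full, "mean")
        slopes = [np.polyfit(sc.ravel(), rec[:, j], 1)[0] for j in range(8)]
        assert np.all(np.abs(np.array(slopes) - 0.8) < 0.15)

    def test_round_trip_serialization(self, tmp_path, trained_linear_vae, linear_dataset):
        path = tmp_path / "model.json"
        vae.save_solution(trained_linear_vae, path)
        back = vae.load_solution(path, linear_dataset.responses)
        assert np.allclose(back.latent_mean, trained_linear_vae.latent_mean)
        assert np.allclose(back.reconstructed, trained_linear_vae.reconstructed)
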