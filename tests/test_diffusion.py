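"""Diffusion algebra: schedule, closed-form corruption, posterior, sampler."""

import numpy as np
import pytest

from scdiffuse.diffusion import (
    DenoiserModel,
    forward_sample,
    load_denoiser,
    make_schedule,
    posterior_mean,
    reverse_step,
    reverse_variance,
    sample,
    save_denoiser,
    training_loss,
)


class TestSchedule:
    def test_linear_endpoints_per_formula(self):
        s = make_schedule(1000, 0.1, 20.0)
        assert s.T == 1000
        np.testing.assert_allclose(s.beta[0], 1e-4)
        np.testing.assert_allclose(s.beta[-1], 0.02)
        assert np.all(np.diff(s.beta) > 0)

    def test_alpha_bar_decreasing_and_terminal_signal_destroyed(self):
        s = make_schedule(1000, 0.1, 20.0)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert 1.0 - s.alpha_bar[-1] > 0.999
        assert s.alpha_bar[-1] < s.alpha_bar[0] < 1.0

    def test_invalid_beta_named_by_index(self):
        # T=2 puts beta_2 = beta_max/T = 10 outside (0, 1)
        with pytest.raises(ValueError, match="beta_2"):
            make_schedule(2, 0.1, 20.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_schedule(1, 0.1, 20.0)
        with pytest.raises(ValueError):
            make_schedule(100, 20.0, 0.1)


class TestForwardSample:
    def test_zero_signal_leaves_scaled_noise(self, rng):
        s = make_schedule(100, 0.1, 20.0)
        eps = rng.normal(size=(4, 3))
        x = forward_sample(s, np.zeros((4, 3)), 40, eps)
        _, _, abar = s.at(40)
        np.testing.assert_allclose(x, np.sqrt(1 - abar) * eps)

    def test_terminal_step_decorrelates_from_signal(self, rng):
        s = make_schedule(200, 0.1, 20.0)
        x0 = rng.normal(size=(1000, 2))
        xT = forward_sample(s, x0, s.T, rng.normal(size=x0.shape))
        corr = np.corrcoef(x0.ravel(), xT.ravel())[0, 1]
        assert abs(corr) < 0.1

    def test_closed_form_matches_iterated_single_steps(self, rng):
        # oracle: iterate x_j = sqrt(1-beta_j) x_{j-1} + sqrt(beta_j) eps_j
        s = make_schedule(50, 0.1, 20.0)
        x0 = rng.normal(size=2)
        n = 20000
        for i in [1, 25, 50]:
            closed = forward_sample(
                s, np.tile(x0, (n, 1)), i, rng.standard_normal((n, 2)))
            chain = np.tile(x0, (n, 1))
            for j in range(1, i + 1):
                beta = s.beta[j - 1]
                chain = (np.sqrt(1 - beta) * chain
                         + np.sqrt(beta) * rng.standard_normal((n, 2)))
            for sample_set in (closed, chain):
                _, _, abar = s.at(i)
                mu_th = np.sqrt(abar) * x0
                var_th = 1 - abar
                se_mu = np.sqrt(var_th / n)
                assert np.all(np.abs(sample_set.mean(0) - mu_th) < 3 * se_mu)
                se_var = var_th * np.sqrt(2.0 / n)
                assert np.all(np.abs(sample_set.var(0) - var_th) < 3 * se_var)

    def test_step_out_of_range(self, rng):
        s = make_schedule(10, 0.1, 2.0)
        with pytest.raises(ValueError, match="range"):
            forward_sample(s, np.zeros((1, 2)), 11, np.zeros((1, 2)))


class TestTrainingLoss:
    def test_zero_model_gives_unit_loss(self):
        class Zero:
            def forward(self, x, i):
                return np.zeros_like(x)

        s = make_schedule(100, 0.1, 20.0)
        batch = np.random.default_rng(0).normal(size=(500, 16))
        loss = training_loss(Zero(), s, batch, np.random.default_rng(1))
        n_el = batch.size
        assert abs(loss - 1.0) < 3 * np.sqrt(2.0 / n_el)

    def test_perfect_denoiser_gives_zero_loss(self):
        # stub replays the loss function's own rng stream to return the
        # exact noise that was injected
        s = make_schedule(100, 0.1, 20.0)
        batch = np.random.default_rng(0).normal(size=(50, 4))

        class Perfect:
            def forward(self, x, i):
                clone = np.random.default_rng(42)
                clone.integers(1, s.T + 1, size=batch.shape[0])
                return clone.standard_normal(batch.shape)

        loss = training_loss(Perfect(), s, batch, np.random.default_rng(42))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_loss_decreases_with_training(self, rng):
        from scdiffuse.diffusion import train_denoiser

        s = make_schedule(50, 0.1, 20.0)
        Z = rng.normal(size=(300, 8)) * np.array([3.0] * 4 + [0.5] * 4)
        model = DenoiserModel(8, width=32, time_dim=8, seed=0)
        hist = train_denoiser(model, s, Z, n_steps=400, seed=0)
        assert np.mean(hist[-50:]) < np.mean(hist[:50])


class TestPosteriorMean:
    def test_zero_eps_hat_is_pure_rescale(self, rng):
        s = make_schedule(100, 0.1, 20.0)
        x = rng.normal(size=(3, 4))
        mu = posterior_mean(s, x, 10, np.zeros_like(x))
        _, alpha, _ = s.at(10)
        np.testing.assert_allclose(mu, x / np.sqrt(alpha))

    def test_algebraic_inversion_recovers_x0(self, rng):
        s = make_schedule(100, 0.1, 20.0)
        x0 = rng.normal(size=(5, 6))
        eps = rng.normal(size=(5, 6))
        for i in [1, 50, 100]:
            x_i = forward_sample(s, x0, i, eps)
            _, _, abar = s.at(i)
            x0_hat = (x_i - np.sqrt(1 - abar) * eps) / np.sqrt(abar)
            np.testing.assert_allclose(x0_hat, x0, atol=1e-6)

    def test_vanishing_beta_limit_leaves_x_unchanged(self, rng):
        s = make_schedule(100, 1e-8, 2e-8)
        x = rng.normal(size=(2, 3))
        mu = posterior_mean(s, x, 50, rng.normal(size=(2, 3)))
        np.testing.assert_allclose(mu, x, atol=1e-3)

    def test_step_zero_rejected(self):
        s = make_schedule(10, 0.1, 2.0)
        with pytest.raises(ValueError):
            posterior_mean(s, np.zeros((1, 2)), 0, np.zeros((1, 2)))


class TestReverseStep:
    def test_null_guidance_identical_to_unguided_under_shared_rng(self, rng):
        s = make_schedule(50, 0.1, 20.0)
        model = DenoiserModel(4, width=16, time_dim=8, seed=0)
        x = rng.normal(size=(6, 4))
        a = reverse_step(s, model, x, 20, rng=np.random.default_rng(3))
        b = reverse_step(s, model, x, 20, guidance=lambda xi, i: np.zeros_like(xi),
                         rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_final_step_is_noise_free(self, rng):
        s = make_schedule(50, 0.1, 20.0)
        model = DenoiserModel(4, width=16, time_dim=8, seed=0)
        x = rng.normal(size=(2, 4))
        a = reverse_step(s, model, x, 1)  # no rng needed at i=1
        eps_hat = model.forward(x, 1)
        np.testing.assert_allclose(a, posterior_mean(s, x, 1, eps_hat))

    def test_injected_variance_follows_selected_mode(self, rng):
        s = make_schedule(50, 0.1, 20.0)
        model = DenoiserModel(3, width=8, time_dim=4, seed=0)
        x = rng.normal(size=(1, 3))
        i, w, n = 25, 0.5, 10000
        draws = np.stack([
            reverse_step(s, model, x, i, w=w, rng=np.random.default_rng(k),
                         variance_mode="exp_w_beta")[0]
            for k in range(n)])
        target = np.exp(w) * s.beta[i - 1]
        se = target * np.sqrt(2.0 / n)
        assert np.all(np.abs(draws.var(axis=0) - target) < 3 * se)

    def test_variance_mode_table(self):
        s = make_schedule(50, 0.1, 20.0)
        beta = s.beta[9]
        assert reverse_variance(s, 10, 0.5, "plain") == pytest.approx(beta)
        assert reverse_variance(s, 10, 0.5, "exp_w_beta") == pytest.approx(np.exp(0.5) * beta)
        assert reverse_variance(s, 10, 0.5, "literal") == pytest.approx(np.exp(0.5 * beta))
        with pytest.raises(ValueError):
            reverse_variance(s, 10, 0.5, "bogus")


class TestSampler:
    def test_fixed_seed_bit_identical(self):
        s = make_schedule(30, 0.1, 20.0)
        model = DenoiserModel(4, width=16, time_dim=8, seed=0)
        a = sample(model, s, n_cells=5, rng=9)
        b = sample(model, s, n_cells=5, rng=9)
        np.testing.assert_array_equal(a, b)

    def test_untrained_model_output_finite(self):
        s = make_schedule(50, 0.1, 20.0)
        model = DenoiserModel(8, width=32, time_dim=8, seed=3)
        out = sample(model, s, n_cells=20, rng=1)
        assert out.shape == (20, 8)
        assert np.all(np.isfinite(out))

    def test_dim_mismatch_rejected(self):
        s = make_schedule(30, 0.1, 20.0)
        model = DenoiserModel(4, width=16, time_dim=8, seed=0)
        with pytest.raises(ValueError, match="latent_dim"):
            sample(model, s, x_init=np.zeros((2, 5)), start_step=10, rng=0)


def test_denoiser_checkpoint_round_trip(tmp_path, rng):
    model = DenoiserModel(6, width=16, time_dim=8, seed=4)
    model.fit_standardization(rng.normal(size=(50, 6)) * 2 + 1)
    save_denoiser(model, tmp_path / "dn.npz")
    loaded = load_denoiser(tmp_path / "dn.npz")
    x = rng.normal(size=(3, 6))
    np.testing.assert_array_equal(model.forward(x, 7), loaded.forward(x, 7))
    np.testing.assert_array_equal(model.loc, loaded.loc)
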