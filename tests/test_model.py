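"""Adversarial-autoencoder losses, gradients and the training loop."""

import numpy as np
import pytest

import imaae.nn as nn
from imaae import (
    AAEConfig,
    build_training_mapping,
    critic_loss,
    generator_loss,
    gradient_penalty,
    reconstruction_loss,
    select_anchor_balanced,
    train,
)
from imaae.model import decode, encode


def _unit_linear_critic(d):
    """Critic D(z) = w.z with ||w|| = 1 (single linear layer)."""
    w = np.full((d, 1), 1.0 / np.sqrt(d))
    return [(w, np.zeros(1))]


def _zero_critic(d):
    return [(np.zeros((d, 1)), np.zeros(1))]


class TestEncodeDecode:
    @pytest.fixture
    def enc(self):
        rng = np.random.default_rng(0)
        backbone = nn.init_mlp([6, 5], rng)
        mu = (rng.normal(size=(5, 3)), np.zeros(3))
        lv = (rng.normal(size=(5, 3)), np.zeros(3))
        return backbone, mu, lv

    def test_zero_noise_limit_returns_mu(self, enc):
        x = np.random.default_rng(1).uniform(size=(4, 6))
        mu, logvar, z = encode(enc, x)  # eps defaults to zero
        np.testing.assert_array_equal(z, mu)

    def test_deterministic_under_seed(self, enc):
        x = np.random.default_rng(1).uniform(size=(4, 6))
        z1 = encode(enc, x, rng=np.random.default_rng(3))[2]
        z2 = encode(enc, x, rng=np.random.default_rng(3))[2]
        np.testing.assert_array_equal(z1, z2)

    def test_reparameterization_std_matches_logvar(self, enc):
        """Sample std of z - mu matches exp(logvar/2) over many draws."""
        x = np.random.default_rng(1).uniform(size=(1, 6))
        rng = np.random.default_rng(5)
        draws = np.stack([encode(enc, x, rng=rng)[2][0] for _ in range(10000)])
        mu, logvar, _ = encode(enc, x)
        np.testing.assert_allclose(
            draws.std(axis=0), np.exp(logvar[0] / 2), rtol=0.05
        )

    def test_width_mismatch_is_error(self, enc):
        with pytest.raises(ValueError, match="width"):
            encode(enc, np.ones((2, 4)))

    def test_decoder_output_nonnegative_any_params(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            dec = nn.init_mlp([3, 8, 10], np.random.default_rng(trial))
            z = rng.normal(scale=5, size=(20, 3))
            out = decode(dec, z)
            assert out.shape == (20, 10)
            assert out.min() >= 0

    def test_zero_decoder_outputs_zero(self):
        dec = [(np.zeros((3, 4)), np.zeros(4)), (np.zeros((4, 6)), np.zeros(6))]
        np.testing.assert_array_equal(decode(dec, np.ones((2, 3))), 0)


class TestLosses:
    def test_reconstruction_identity_and_closed_forms(self):
        assert reconstruction_loss([[1.0, 2.0]], [[1.0, 2.0]]) == 0.0
        assert reconstruction_loss([[1.0, 0.0]], [[0.0, 0.0]]) == 1.0
        # ((1+4)+(9+16))/2 = 15
        assert reconstruction_loss([[1, 2], [3, 4]], [[0, 0], [0, 0]]) == 15.0

    def test_reconstruction_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            reconstruction_loss(np.ones((2, 3)), np.ones((3, 2)))

    def test_gp_zero_for_unit_gradient_critic(self):
        rng = np.random.default_rng(0)
        critic = _unit_linear_critic(4)
        z = rng.normal(size=(10, 4))
        assert gradient_penalty(critic, z, z + 1, 10.0, np.random.default_rng(1)) == pytest.approx(0.0, abs=1e-12)

    def test_gp_lambda_for_constant_critic(self):
        rng = np.random.default_rng(0)
        critic = _zero_critic(4)
        z = rng.normal(size=(10, 4))
        lam = 7.5
        assert gradient_penalty(critic, z, z + 1, lam, np.random.default_rng(1)) == pytest.approx(lam)

    def test_gp_negative_lambda_is_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            gradient_penalty(_zero_critic(2), np.ones((2, 2)), np.ones((2, 2)), -1.0, np.random.default_rng(0))

    def test_input_gradient_matches_finite_differences(self):
        """Analytic critic input gradient agrees with central differences."""
        rng = np.random.default_rng(2)
        critic = nn.init_mlp([3, 4, 2, 1], rng)  # <= 8 hidden units
        z = rng.normal(size=(6, 3))
        g = nn.critic_input_grad(critic, z)
        h = 1e-6
        for i in range(6):
            for j in range(3):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += h
                zm[i, j] -= h
                fd = (nn.critic_score(critic, zp)[i] - nn.critic_score(critic, zm)[i]) / (2 * h)
                assert abs(fd - g[i, j]) < 1e-4

    def test_gp_param_gradient_matches_finite_differences(self):
        """The double-backprop weight gradient of the penalty agrees with FD."""
        rng = np.random.default_rng(3)
        critic = nn.init_mlp([3, 4, 1], rng)
        z_hat = rng.normal(size=(5, 3))
        lam = 10.0
        _, grads = nn.gradient_penalty_param_grads(critic, z_hat, lam)
        h = 1e-6
        for layer in range(len(critic)):
            W, b = critic[layer]
            for idx in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
                pert = [(w.copy(), bb.copy()) for w, bb in critic]
                pert[layer][0][idx] += h
                up = nn.gradient_penalty_value(pert, z_hat, lam)
                pert[layer][0][idx] -= 2 * h
                dn = nn.gradient_penalty_value(pert, z_hat, lam)
                fd = (up - dn) / (2 * h)
                assert abs(fd - grads[layer][0][idx]) < 1e-4

    def test_critic_loss_constant_critic_is_lambda(self):
        critic = [(np.zeros((3, 1)), np.array([2.0]))]  # D == 2 everywhere
        rng = np.random.default_rng(0)
        z = rng.normal(size=(50, 3))
        lam = 10.0
        # -2 + 2 + lam*(0-1)^2
        assert critic_loss(critic, z, z + 1, lam, np.random.default_rng(1)) == pytest.approx(lam)

    def test_critic_loss_identical_batches_cancels(self):
        rng = np.random.default_rng(4)
        critic = nn.init_mlp([3, 4, 1], rng)
        z = rng.normal(size=(30, 3))
        loss = critic_loss(critic, z, z, 0.0, np.random.default_rng(0))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_critic_loss_law_of_large_numbers(self):
        """For D(z)=w.z with ||w||=1, L_D -> w.m when fakes have mean m."""
        critic = _unit_linear_critic(4)
        rng = np.random.default_rng(5)
        n = 100_000
        m_shift = np.array([1.0, -0.5, 0.2, 0.0])
        z_real = rng.normal(size=(n, 4))
        z_fake = rng.normal(size=(n, 4)) + m_shift
        loss = critic_loss(critic, z_real, z_fake, 0.0, np.random.default_rng(1))
        expected = float(np.full(4, 1 / np.sqrt(4)) @ m_shift)
        # 3 sigma of the mean-difference estimator
        tol = 3 * np.sqrt(2.0 / n)
        assert abs(loss - expected) < tol

    def test_generator_loss_identities(self):
        critic = [(np.zeros((3, 1)), np.array([4.0]))]
        z = np.random.default_rng(0).normal(size=(10, 3))
        assert generator_loss(critic, z) == pytest.approx(-4.0)
        # algebraic identity with the critic loss's fake term
        rng = np.random.default_rng(1)
        critic2 = nn.init_mlp([3, 4, 1], rng)
        fake_term = float(nn.critic_score(critic2, z).mean())
        assert generator_loss(critic2, z) == pytest.approx(-fake_term)

    def test_generator_step_raises_fake_scores(self):
        """One gradient step on L_G increases the critic's mean score of fakes."""
        rng = np.random.default_rng(6)
        critic = _unit_linear_critic(3)
        z = rng.normal(size=(20, 3))
        before = nn.critic_score(critic, z).mean()
        # gradient of -mean(D) wrt z is -w/n per row; step against it
        grad = -nn.critic_input_grad(critic, z) / len(z)
        z2 = z - 0.1 * grad
        assert nn.critic_score(critic, z2).mean() > before


class TestTraining:
    def _setup(self, prepped_small, **cfg_kwargs):
        prep, graph = prepped_small
        anchors = select_anchor_balanced(prep, graph, seed=0)
        mapping = build_training_mapping(prep, anchors, graph, seed=0)
        cfg = AAEConfig.for_data(prep.n_genes, latent_dim=8, epochs=cfg_kwargs.pop("epochs", 2),
                                 batch_size=64, seed=cfg_kwargs.pop("seed", 0), **cfg_kwargs)
        return prep, anchors, mapping, cfg

    def test_history_length_and_finiteness(self, prepped_small):
        prep, anchors, mapping, cfg = self._setup(prepped_small)
        model = train(prep, mapping, anchors, cfg)
        assert len(model.history) == cfg.epochs
        assert np.isfinite(np.asarray(model.history)).all()

    def test_bitwise_deterministic_under_seed(self, prepped_small):
        prep, anchors, mapping, cfg = self._setup(prepped_small, seed=3)
        h1 = train(prep, mapping, anchors, cfg).history
        prep, anchors, mapping, cfg = self._setup(prepped_small, seed=3)
        h2 = train(prep, mapping, anchors, cfg).history
        assert h1 == h2

    def test_reconstruction_loss_decreases(self, prepped_small):
        """L_R drops by at least half from the first to the last epoch."""
        wins = 0
        for seed in (0, 1, 2):
            prep, anchors, mapping, cfg = self._setup(
                prepped_small, epochs=15, seed=seed, learning_rate=3e-3)
            model = train(prep, mapping, anchors, cfg)
            if model.history[-1][0] <= 0.5 * model.history[0][0]:
                wins += 1
        assert wins >= 2

    def test_generator_loss_bookkeeping_identity(self, prepped_small):
        """Recorded L_G of the final step equals -mean critic score of its fakes."""
        prep, anchors, mapping, cfg = self._setup(prepped_small)
        model = train(prep, mapping, anchors, cfg)
        z = model.last_step["z_fake"]
        assert model.last_step["l_g"] == pytest.approx(
            -float(nn.critic_score(model.critic, z).mean()), rel=1e-12
        )

    def test_oversized_batch_warns_and_trains(self, prepped_small):
        prep, anchors, mapping, _ = self._setup(prepped_small)
        cfg = AAEConfig.for_data(prep.n_genes, latent_dim=8, epochs=1, batch_size=10_000)
        with pytest.warns(UserWarning, match="full-batch"):
            model = train(prep, mapping, anchors, cfg)
        assert len(model.history) == 1

    def test_adversary_contains_latent_scale(self, prepped_small):
        """The critic keeps the latent near the N(0, I) prior scale, while an
        unconstrained autoencoder lets it drift far from it."""
        norms = {}
        for mode in ("full", "ae_only"):
            prep, anchors, mapping, cfg = self._setup(
                prepped_small, epochs=150, seed=0, learning_rate=3e-3, mode=mode)
            model = train(prep, mapping, anchors, cfg)
            mu, _, _ = encode(model, np.asarray(prep.values, float))
            norms[mode] = float(np.linalg.norm(mu, axis=1).mean())
        d = 8
        # E||z|| under the prior is ~sqrt(d); the adversary should hold the
        # latent within a small multiple of that, the plain AE should not
        assert norms["full"] <= 2.5 * np.sqrt(d)
        assert norms["full"] < norms["ae_only"]

    def test_model_save_load_round_trip(self, prepped_small, tmp_path):
        prep, anchors, mapping, cfg = self._setup(prepped_small)
        model = train(prep, mapping, anchors, cfg)
        model.save(tmp_path / "m.npz")
        from imaae import TrainedAAE

        back = TrainedAAE.load(tmp_path / "m.npz")
        x = np.asarray(prep.values, float)[:5]
        np.testing.assert_array_equal(encode(model, x)[0], encode(back, x)[0])
        assert back.config.latent_dim == cfg.latent_dim


class TestConfigValidation:
    def test_width_consistency_enforced(self):
        with pytest.raises(ValueError, match="decoder"):
            AAEConfig(encoder_widths=[10, 4], decoder_widths=[4, 9])
        with pytest.raises(ValueError, match="critic"):
            AAEConfig(encoder_widths=[10, 4], critic_widths=[4, 2])

    def test_defaults_mirror_encoder(self):
        cfg = AAEConfig()
        assert cfg.latent_dim == 250
        assert cfg.decoder_widths == [250, 500, 1000, 2000]
        assert cfg.critic_widths[-1] == 1 and cfg.critic_widths[0] == 250

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            AAEConfig(encoder_widths=[10, 4], mode="both")
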