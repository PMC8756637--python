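"""The variational machinery: cluster posterior, encoder/decoder contracts,
prior KL, consistency loss, imputation, EM initialisation, checkpoints."""

import numpy as np
import pytest
from scipy.special import logsumexp as sp_logsumexp

from pairedvae.model import (ATACDecoderOutput, GMMPrior, LatentPosterior,
                             ModelConfig, MultiViewVAE, RNADecoderOutput,
                             cluster_posterior, consistency_loss, elbo_terms,
                             impute, init_gmm_prior, load_checkpoint,
                             save_checkpoint)

SMALL_CFG = dict(K=3, latent_dim=4, hidden_dim=16, shared_dim=24,
                 n_heads=4, head_dim=4)


@pytest.fixture()
def small_model(rng):
    model = MultiViewVAE(n_genes=12, n_peaks=20, cfg=ModelConfig(**SMALL_CFG),
                         rng=np.random.default_rng(0))
    x = rng.poisson(2.0, (10, 12)).astype(float)
    y = np.abs(rng.standard_normal((10, 20))) * (rng.random((10, 20)) < 0.5)
    return model, x, y


class TestClusterPosterior:
    def test_single_component_is_one(self):
        prior = GMMPrior.standard_normal(3)
        resp = cluster_posterior(np.random.default_rng(0).standard_normal((5, 3)), prior)
        np.testing.assert_array_equal(resp, np.ones((5, 1)))

    def test_symmetric_two_component_midpoint(self):
        prior = GMMPrior(K=2, log_pi=np.log([0.5, 0.5]),
                         mu=np.array([[-1.0] * 3, [1.0] * 3]),
                         sigma=np.ones((2, 3)))
        resp = cluster_posterior(np.zeros((1, 3)), prior)
        np.testing.assert_allclose(resp, [[0.5, 0.5]], atol=1e-12)

    def test_matches_dense_density_oracle(self, rng):
        K, D = 3, 4
        mu = rng.standard_normal((K, D))
        sigma = np.exp(rng.standard_normal((K, D)) * 0.3)
        pi = rng.dirichlet(np.ones(K))
        prior = GMMPrior(K=K, log_pi=np.log(pi), mu=mu, sigma=sigma)
        z = rng.standard_normal((6, D))
        resp = cluster_posterior(z, prior)
        # brute-force normalisation of the Gaussian densities
        dens = np.empty((6, K))
        for i in range(6):
            for k in range(K):
                dens[i, k] = pi[k] * np.prod(
                    np.exp(-0.5 * ((z[i] - mu[k]) / sigma[k]) ** 2)
                    / (np.sqrt(2 * np.pi) * sigma[k]))
        oracle = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(resp, oracle, atol=1e-10)

    def test_rows_sum_to_one(self, rng):
        prior = GMMPrior(K=4, log_pi=np.log(np.full(4, 0.25)),
                         mu=rng.standard_normal((4, 5)), sigma=np.ones((4, 5)))
        resp = cluster_posterior(rng.standard_normal((50, 5)) * 10, prior)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)


class TestEncoder:
    def test_posterior_contracts(self, small_model):
        model, x, y = small_model
        post = model.encode(x, y)
        assert (post.sigma_z > 0).all()
        np.testing.assert_allclose(post.resp.sum(axis=1), 1.0, atol=1e-5)

    def test_deterministic_mode_returns_mean(self, small_model):
        model, x, y = small_model
        post = model.encode(x, y, eps=None)
        np.testing.assert_array_equal(post.z_sample, post.mu_z)

    def test_duplicated_cells_identical_rows_eval(self, small_model):
        model, x, y = small_model
        x2 = np.vstack([x, x[:1]])
        y2 = np.vstack([y, y[:1]])
        post = model.encode(x2, y2)
        np.testing.assert_allclose(post.mu_z[-1], post.mu_z[0], rtol=1e-6)

    def test_permutation_equivariance_eval(self, small_model, rng):
        model, x, y = small_model
        perm = rng.permutation(x.shape[0])
        post = model.encode(x, y)
        post_p = model.encode(x[perm], y[perm])
        np.testing.assert_allclose(post_p.mu_z, post.mu_z[perm], rtol=1e-5, atol=1e-6)

    def test_forward_is_pure_in_eval_mode(self, small_model):
        model, x, y = small_model
        a = model.encode(x, y)
        b = model.encode(x, y)
        np.testing.assert_array_equal(a.mu_z, b.mu_z)


class TestDecoders:
    def test_outputs_strictly_positive_and_bounded(self, small_model, rng):
        model, x, y = small_model
        post = model.encode(x, y)
        rna_out, atac_out = model.decode(post)
        assert (rna_out.alpha > 0).all() and (rna_out.beta > 0).all()
        assert (atac_out.mu > 0).all()
        assert ((atac_out.tau > 0) & (atac_out.tau < 1)).all()

    def test_cluster_attention_normalised(self, small_model):
        from pairedvae.autodiff import Tensor, softmax
        model, x, y = small_model
        resp = Tensor(np.random.default_rng(1).dirichlet(np.ones(3), size=7))
        w = softmax(model.dec_rna.cluster_attn(resp), axis=-1)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)
        assert (w.data >= 0).all()

    def test_attention_rows_normalised(self, small_model):
        from pairedvae.autodiff import Tensor
        model, x, y = small_model
        h = Tensor(np.random.default_rng(2).standard_normal((5, 16)))
        attn = model.dec_atac.mha.attention_weights(h)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_head_matches_manual_reference(self):
        """One attention head equals a hand-composed scaled-dot-product."""
        from pairedvae.autodiff import Tensor
        from pairedvae.nn import MultiHeadSelfAttention
        rng = np.random.default_rng(3)
        mha = MultiHeadSelfAttention(width=8, n_heads=1, head_dim=8, rng=rng,
                                     dtype=np.float64)
        h = rng.standard_normal((4, 8))
        out = mha(Tensor(h)).data
        # manual: one token of 8 dims per cell, one head
        X = h.reshape(4, 1, 8)
        q = X @ mha.Wq.data[0]
        k = X @ mha.Wk.data[0]
        v = X @ mha.Wv.data[0]
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(8)
        attn = np.exp(scores - scores.max(-1, keepdims=True))
        attn /= attn.sum(-1, keepdims=True)
        ref = ((attn @ v) @ mha.Wo.data).reshape(4, 8)
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_multi_head_matches_manual_reference(self):
        from pairedvae.autodiff import Tensor
        from pairedvae.nn import MultiHeadSelfAttention
        rng = np.random.default_rng(4)
        H, d = 2, 4
        mha = MultiHeadSelfAttention(width=8, n_heads=H, head_dim=d, rng=rng,
                                     dtype=np.float64)
        h = rng.standard_normal((3, 8))
        out = mha(Tensor(h)).data
        X = h.reshape(3, 2, 4)          # 2 tokens of 4 dims
        heads = []
        for i in range(H):
            q = X @ mha.Wq.data[i]
            k = X @ mha.Wk.data[i]
            v = X @ mha.Wv.data[i]
            s = q @ np.swapaxes(k, -1, -2) / np.sqrt(d)
            a = np.exp(s - s.max(-1, keepdims=True))
            a /= a.sum(-1, keepdims=True)
            heads.append(a @ v)
        concat = np.concatenate(heads, axis=-1)       # (3, 2, 8)
        ref = (concat @ mha.Wo.data).reshape(3, 8)
        np.testing.assert_allclose(out, ref, atol=1e-6)


class TestElboTerms:
    def test_k1_standard_prior_matches_closed_form(self, rng):
        """Monte-Carlo prior KL vs the analytic single-Gaussian KL."""
        n, D = 6, 4
        mu = rng.standard_normal((n, D)) * 0.5
        sigma = np.exp(rng.standard_normal((n, D)) * 0.2)
        prior = GMMPrior.standard_normal(D)
        draws = []
        for _ in range(10_000):
            z = mu + sigma * rng.standard_normal((n, D))
            post = LatentPosterior(mu_z=mu, sigma_z=sigma, z_sample=z,
                                   resp=np.ones((n, 1)))
            draws.append(elbo_terms(np.zeros((n, 1)), np.zeros((n, 1)),
                                    post, None, None, prior).kl_prior)
        closed = 0.5 * np.sum(mu ** 2 + sigma ** 2 - np.log(sigma ** 2) - 1) / n
        mc = np.mean(draws)
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(mc - closed) < 4 * se + 1e-4

    def test_posterior_equal_to_prior_component_gives_zero_expectation(self, rng):
        n, D = 400, 3
        prior = GMMPrior.standard_normal(D)
        mu = np.zeros((n, D))
        sigma = np.ones((n, D))
        z = rng.standard_normal((n, D))
        post = LatentPosterior(mu_z=mu, sigma_z=sigma, z_sample=z,
                               resp=np.ones((n, 1)))
        rep = elbo_terms(np.zeros((n, 1)), np.zeros((n, 1)), post, None, None, prior)
        assert abs(rep.kl_prior) < 0.2    # MC noise around 0

    def test_duplicating_batch_preserves_per_cell_means(self, small_model):
        model, x, y = small_model
        post = model.encode(x, y)
        rna_out, atac_out = model.decode(post)
        prior = model.get_prior()
        y_t = model.zip_target(y)
        one = elbo_terms(x, y_t, post, rna_out, atac_out, prior)
        dup = LatentPosterior(mu_z=np.vstack([post.mu_z] * 2),
                              sigma_z=np.vstack([post.sigma_z] * 2),
                              z_sample=np.vstack([post.z_sample] * 2),
                              resp=np.vstack([post.resp] * 2))
        rna2 = RNADecoderOutput(alpha=np.vstack([rna_out.alpha] * 2),
                                beta=np.vstack([rna_out.beta] * 2))
        atac2 = ATACDecoderOutput(mu=np.vstack([atac_out.mu] * 2),
                                  tau=np.vstack([atac_out.tau] * 2))
        two = elbo_terms(np.vstack([x] * 2), np.vstack([y_t] * 2), dup, rna2,
                         atac2, prior)
        # per-cell means unchanged => summed terms double exactly
        assert two.nll_rna == pytest.approx(one.nll_rna, rel=1e-12)
        assert two.nll_atac == pytest.approx(one.nll_atac, rel=1e-12)
        assert two.kl_prior == pytest.approx(one.kl_prior, rel=1e-12)
        assert two.n_cells == 2 * one.n_cells

    def test_training_loss_matches_reference_terms(self, small_model):
        """The differentiable objective agrees with the numpy reference path."""
        model, x, y = small_model
        model.eval()
        eps = np.zeros((x.shape[0], model.cfg.latent_dim))
        post = model.encode(x, y, eps=eps)
        rna_out, atac_out = model.decode(post)
        ref = elbo_terms(x, model.zip_target(y), post, rna_out, atac_out,
                         model.get_prior())

        class _FixedEps:
            def standard_normal(self, shape):
                return eps
        total, terms = model.loss_t(x, y, _FixedEps(), with_consistency=False)
        assert terms["nll_rna"].item() == pytest.approx(ref.nll_rna, rel=1e-4)
        assert terms["nll_atac"].item() == pytest.approx(ref.nll_atac, rel=1e-4)
        assert terms["kl_prior"].item() == pytest.approx(ref.kl_prior, rel=1e-3, abs=1e-3)


class TestConsistencyLoss:
    def _post(self, mu, sigma):
        n, d = mu.shape
        return LatentPosterior(mu_z=mu, sigma_z=sigma, z_sample=mu.copy(),
                               resp=np.ones((n, 1)))

    def test_identical_posteriors_zero(self, rng):
        mu = rng.standard_normal((4, 3))
        sigma = np.exp(rng.standard_normal((4, 3)) * 0.3)
        p = self._post(mu, sigma)
        assert consistency_loss(p, self._post(mu.copy(), sigma.copy()),
                                self._post(mu.copy(), sigma.copy())) == pytest.approx(0.0, abs=1e-10)

    def test_unit_shift_hand_value(self):
        d = 4
        p = self._post(np.zeros((2, d)), np.ones((2, d)))
        q = self._post(np.ones((2, d)), np.ones((2, d)))
        # KL(N(0,1)||N(1,1)) = 0.5 per dimension, one auxiliary term
        assert consistency_loss(p, q, None) == pytest.approx(0.5 * d, abs=1e-12)

    def test_non_negative(self, rng):
        for _ in range(10):
            p = self._post(rng.standard_normal((3, 2)),
                           np.exp(rng.standard_normal((3, 2))))
            q = self._post(rng.standard_normal((3, 2)),
                           np.exp(rng.standard_normal((3, 2))))
            assert consistency_loss(p, q, None) >= -1e-6

    def test_shape_mismatch_raises(self, rng):
        p = self._post(np.zeros((3, 2)), np.ones((3, 2)))
        q = self._post(np.zeros((4, 2)), np.ones((4, 2)))
        with pytest.raises(ValueError):
            consistency_loss(p, q, None)


class TestImpute:
    def test_gamma_and_poisson_means(self):
        rna = RNADecoderOutput(alpha=np.array([[4.0]]), beta=np.array([[2.0]]))
        atac = ATACDecoderOutput(mu=np.array([[0.7]]), tau=np.array([[0.5]]))
        imputed_rna, imputed_atac = impute(rna, atac)
        assert imputed_rna[0, 0] == pytest.approx(2.0)
        assert imputed_atac[0, 0] == pytest.approx(0.7)

    def test_non_negative_finite(self, small_model):
        model, x, y = small_model
        post = model.encode(x, y)
        imputed_rna, imputed_atac = impute(*model.decode(post))
        for m in (imputed_rna, imputed_atac):
            assert np.isfinite(m).all() and (m >= 0).all()


class TestInitGmmPrior:
    def test_recovers_two_separated_components(self, rng):
        n = 2000
        means = np.array([[0.0, 0.0], [10.0, 10.0]])
        labels = rng.random(n) < 0.4
        data = means[labels.astype(int)] + rng.standard_normal((n, 2))
        prior = init_gmm_prior(data, 2, seed=0)
        order = np.argsort(prior.mu[:, 0])
        np.testing.assert_allclose(prior.mu[order], means, atol=0.1)
        np.testing.assert_allclose(np.exp(prior.log_pi)[order],
                                   [1 - labels.mean(), labels.mean()], atol=0.05)

    def test_k1_closed_form(self, rng):
        data = rng.standard_normal((500, 3)) * 1.7 + 0.3
        prior = init_gmm_prior(data, 1, seed=0)
        np.testing.assert_allclose(prior.mu[0], data.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(prior.sigma[0], data.std(axis=0), atol=1e-5)

    def test_deterministic(self, rng):
        data = rng.standard_normal((300, 4))
        a = init_gmm_prior(data, 3, seed=5)
        b = init_gmm_prior(data, 3, seed=5)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.log_pi, b.log_pi)

    def test_too_few_cells_raises(self, rng):
        with pytest.raises(ValueError):
            init_gmm_prior(rng.standard_normal((2, 3)), 5, seed=0)


class TestPriorType:
    def test_weights_must_normalise(self):
        with pytest.raises(ValueError, match="sum"):
            GMMPrior(K=2, log_pi=np.log([0.5, 0.4]), mu=np.zeros((2, 2)),
                     sigma=np.ones((2, 2)))

    def test_sigma_floor_enforced(self):
        with pytest.raises(ValueError, match="floor"):
            GMMPrior(K=1, log_pi=np.zeros(1), mu=np.zeros((1, 2)),
                     sigma=np.full((1, 2), 1e-6))


class TestCheckpoint:
    def test_round_trip_bit_exact(self, small_model, tmp_path):
        model, x, y = small_model
        model.set_prior(init_gmm_prior(np.random.default_rng(0).standard_normal((50, 4)),
                                       3, seed=0))
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        for p, q in zip(model.parameters(), clone.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
        a = model.encode(x, y)
        b = clone.encode(x, y)
        np.testing.assert_array_equal(a.mu_z, b.mu_z)
        np.testing.assert_array_equal(a.resp, b.resp)


class TestModelConfig:
    def test_head_width_consistency(self):
        with pytest.raises(ValueError):
            ModelConfig(K=2, n_heads=8, head_dim=10, hidden_dim=128)

    def test_latent_dim_minimum(self):
        with pytest.raises(ValueError):
            ModelConfig(K=2, latent_dim=1)
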