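import numpy as np
import pytest
from scipy import stats

from omicsfuse.autodiff import Tensor
from omicsfuse.io import PairedOmics, normalize_rna
from omicsfuse.model import (
    DecoderParams,
    FusionWeights,
    LossWeights,
    ModelConfig,
    ZINBParams,
    bernoulli_ce,
    bernoulli_decode,
    fuse,
    impute,
    init_bernoulli_decoder,
    init_zinb_decoder,
    total_loss,
    train,
    zinb_decode,
    zinb_nll,
)
from omicsfuse.synthetic import SyntheticSpec, generate_paired_dataset


def uniform_params(shape, pi=0.0, mu=1.0, theta=1.0):
    return ZINBParams(Pi=np.full(shape, pi), M_r=np.full(shape, mu),
                      Theta=np.full(shape, theta))


class TestFuse:
    def test_zero_weights_return_common_embedding(self, rng):
        Z = rng.normal(size=(3, 4))
        out = fuse(Z, rng.normal(size=(3, 4)), rng.normal(size=(3, 4)),
                   FusionWeights(0.0, 0.0))
        np.testing.assert_array_equal(out, Z)

    def test_linearity(self, rng):
        M = rng.normal(size=(2, 3))
        np.testing.assert_allclose(fuse(M, M, M, FusionWeights(1.0, 1.0)), 3 * M)

    def test_matches_elementwise_oracle(self, rng):
        a, b, c = (rng.normal(size=(4, 5)) for _ in range(3))
        out = fuse(a, b, c, FusionWeights(0.3, 0.7))
        np.testing.assert_allclose(out, a + 0.3 * b + 0.7 * c, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse(rng.normal(size=(2, 3)), rng.normal(size=(3, 3)),
                 rng.normal(size=(2, 3)), FusionWeights())


class TestZinbNll:
    def test_pure_nb_closed_form_at_zero(self):
        # NB(0; mu=1, theta=1) = 0.5
        x = np.zeros((1, 1))
        val = zinb_nll(x, uniform_params((1, 1)))
        assert val == pytest.approx(-np.log(0.5), abs=1e-12)

    def test_mixture_closed_form_at_zero(self):
        x = np.zeros((1, 1))
        val = zinb_nll(x, uniform_params((1, 1), pi=0.5))
        assert val == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_matches_nbinom_logpmf_on_grid(self):
        xs, mus, thetas = np.meshgrid(np.arange(8.0), [0.5, 2.0, 7.0],
                                      [0.3, 1.0, 4.0])
        x, mu, th = (a.ravel()[None, :] for a in (xs, mus, thetas))
        params = ZINBParams(Pi=np.zeros_like(x), M_r=mu, Theta=th)
        # scipy's NB parameterization: n = theta, p = theta / (theta + mu)
        expected = -stats.nbinom.logpmf(x, th, th / (th + mu)).mean()
        assert zinb_nll(x, params) == pytest.approx(expected, abs=1e-10)

    def test_poisson_limit_at_large_dispersion(self):
        x = np.arange(11.0)[None, :]
        params = ZINBParams(Pi=np.zeros_like(x), M_r=np.full_like(x, 3.0),
                            Theta=np.full_like(x, 1e6))
        expected = -stats.poisson.logpmf(x, 3.0).mean()
        assert zinb_nll(x, params) == pytest.approx(expected, abs=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            zinb_nll(np.array([[-1.0]]), uniform_params((1, 1)))
        with pytest.raises(ValueError):
            zinb_nll(np.zeros((1, 1)), uniform_params((1, 1), pi=1.0))
        with pytest.raises(ValueError):
            zinb_nll(np.zeros((1, 1)), uniform_params((1, 1), theta=0.0))

    def test_mu_scan_recovers_sample_mean(self):
        # for NB data with theta fixed, the NLL over a mu-grid is minimized
        # near the empirical mean
        rng = np.random.default_rng(0)
        theta, mu_true, n = 2.0, 6.0, 5000
        x = rng.poisson(rng.gamma(theta, mu_true / theta, size=n))[None, :].astype(float)
        grid = np.linspace(3.0, 10.0, 141)
        nlls = [zinb_nll(x, ZINBParams(Pi=np.zeros_like(x),
                                       M_r=np.full_like(x, m),
                                       Theta=np.full_like(x, theta)))
                for m in grid]
        best = grid[int(np.argmin(nlls))]
        assert abs(best - x.mean()) / x.mean() <= 0.05


class TestDecoders:
    def _zero_decoder(self, d, hidden, out, kind="zinb"):
        init = init_zinb_decoder if kind == "zinb" else init_bernoulli_decoder
        dec = init(d, hidden, out, np.random.default_rng(0))
        dec.trunk[0].data[:] = 0.0
        dec.trunk[1].data[:] = 0.0
        for W, b in dec.heads.values():
            W.data[:] = 0.0
            b.data[:] = 0.0
        return dec

    def test_zero_network_gives_neutral_parameters(self):
        dec = self._zero_decoder(3, 4, 5)
        out = zinb_decode(np.ones((2, 3)), dec)
        np.testing.assert_allclose(out.Pi, 0.5)
        np.testing.assert_allclose(out.M_r, 1.0)
        np.testing.assert_allclose(out.Theta, 1.0)
        dec_b = self._zero_decoder(3, 4, 5, kind="bernoulli")
        np.testing.assert_allclose(bernoulli_decode(np.ones((2, 3)), dec_b), 0.5)

    def test_output_ranges(self, rng):
        dec = init_zinb_decoder(4, 8, 6, rng)
        out = zinb_decode(rng.normal(size=(3, 4)), dec)
        assert ((out.Pi > 0) & (out.Pi < 1)).all()
        assert (out.M_r > 0).all() and (out.Theta > 0).all()
        dec_b = init_bernoulli_decoder(4, 8, 6, rng)
        m = bernoulli_decode(rng.normal(size=(3, 4)), dec_b)
        assert ((m > 0) & (m < 1)).all()

    def test_linear_heads_match_hand_oracle(self, rng):
        # identity trunk (hidden = d, W = I, b = 0) on positive Z keeps the
        # ELU inactive, so heads are plain affine maps
        d = 3
        dec = init_zinb_decoder(d, d, 2, rng)
        dec.trunk[0].data[:] = np.eye(d)
        dec.trunk[1].data[:] = 0.0
        Z = np.abs(rng.normal(size=(2, d))) + 0.1
        out = zinb_decode(Z, dec)
        W_pi, b_pi = dec.heads["pi"]
        from scipy.special import expit
        np.testing.assert_allclose(out.Pi, np.clip(expit(Z @ W_pi.data + b_pi.data),
                                                   1e-7, 1 - 1e-7), atol=1e-10)
        W_mu, b_mu = dec.heads["mu"]
        np.testing.assert_allclose(out.M_r, np.exp(Z @ W_mu.data + b_mu.data),
                                   atol=1e-10)


class TestBernoulliCe:
    def test_closed_forms(self):
        assert bernoulli_ce(np.array([[1.0]]), np.array([[0.5]])) == \
            pytest.approx(np.log(2.0), abs=1e-12)
        assert bernoulli_ce(np.array([[0.0]]), np.array([[1e-12]])) == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        x = (rng.random((4, 5)) > 0.5).astype(float)
        u = rng.uniform(0.05, 0.95, size=(4, 5))
        expected = -np.mean(x * np.log(u) + (1 - x) * np.log(1 - u))
        assert bernoulli_ce(x, u) == pytest.approx(expected, abs=1e-12)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_ce(np.array([[0.5]]), np.array([[0.5]]))


class TestTotalLoss:
    def _inputs(self, rng):
        x_r = rng.poisson(3.0, size=(4, 5)).astype(float)
        x_a = (rng.random((4, 6)) > 0.5).astype(float)
        params = ZINBParams(Pi=rng.uniform(0.1, 0.9, (4, 5)),
                            M_r=rng.uniform(0.5, 5.0, (4, 5)),
                            Theta=rng.uniform(0.5, 5.0, (4, 5)),
                            M_a=rng.uniform(0.1, 0.9, (4, 6)))
        return x_r, x_a, params

    def test_reduction_and_linearity(self, rng):
        x_r, x_a, params = self._inputs(rng)
        base = total_loss(x_r, x_a, params, 0.7, LossWeights(0.0, 0.0))
        assert base == pytest.approx(zinb_nll(x_r, params), abs=1e-12)
        l1 = total_loss(x_r, x_a, params, 0.7, LossWeights(0.2, 0.0))
        l2 = total_loss(x_r, x_a, params, 0.7, LossWeights(0.4, 0.0))
        assert l2 - l1 == pytest.approx(0.2 * bernoulli_ce(x_a, params.M_a),
                                        abs=1e-10)

    def test_composition_of_components(self, rng):
        x_r, x_a, params = self._inputs(rng)
        w = LossWeights(0.3, 1.7)
        expected = (zinb_nll(x_r, params) + 0.3 * bernoulli_ce(x_a, params.M_a)
                    + 1.7 * 0.9)
        assert total_loss(x_r, x_a, params, 0.9, w) == pytest.approx(expected,
                                                                     abs=1e-10)

    def test_invariant_to_cell_permutation(self, rng):
        x_r, x_a, params = self._inputs(rng)
        perm = rng.permutation(4)
        permuted = ZINBParams(Pi=params.Pi[perm], M_r=params.M_r[perm],
                              Theta=params.Theta[perm], M_a=params.M_a[perm])
        assert total_loss(x_r[perm], x_a[perm], permuted, 0.5, LossWeights()) == \
            pytest.approx(total_loss(x_r, x_a, params, 0.5, LossWeights()),
                          abs=1e-9)


@pytest.fixture(scope="module")
def trained_small(small_paired):
    data, truth, _ = small_paired
    cfg = ModelConfig(pretrain_epochs=40, joint_epochs=60, seed=0)
    state, Z, params = train(data, cfg)
    return data, truth, cfg, state, Z, params


class TestTrain:
    def test_deterministic(self, small_paired):
        data, _, _ = small_paired
        cfg = ModelConfig(pretrain_epochs=5, joint_epochs=8, seed=4)
        s1, Z1, _ = train(data, cfg)
        s2, Z2, _ = train(data, cfg)
        assert abs(s1.loss_trace[-1][1] - s2.loss_trace[-1][1]) <= 1e-6
        np.testing.assert_array_equal(Z1, Z2)

    def test_joint_loss_decreases(self, trained_small):
        state = trained_small[3]
        losses = [row[1] for row in state.loss_trace]
        assert losses[50] < losses[0]

    def test_embedding_recovers_clusters(self, trained_small):
        from omicsfuse.smoothing import cluster, evaluate
        _, truth, _, _, Z, _ = trained_small
        _, ari = evaluate(cluster(Z, 3, seed=0), truth)
        assert ari >= 0.9

    def test_returned_params_satisfy_invariants(self, trained_small):
        *_, params = trained_small
        assert ((params.Pi > 0) & (params.Pi < 1)).all()
        assert (params.M_r > 0).all() and (params.Theta > 0).all()
        assert ((params.M_a > 0) & (params.M_a < 1)).all()


class TestImpute:
    def test_shapes_and_ranges(self, trained_small):
        data, _, _, state, _, _ = trained_small
        m_r, m_a = impute(state, data)
        assert m_r.shape == data.rna_counts.shape
        assert m_a.shape == data.atac_counts.shape
        assert (m_r > 0).all() and ((m_a > 0) & (m_a < 1)).all()

    def test_untrained_model_rejected(self, trained_small):
        import dataclasses
        data, _, _, state, _, _ = trained_small
        broken = dataclasses.replace(state, trained=False)
        with pytest.raises(RuntimeError):
            impute(broken, data)

    def test_imputed_means_beat_raw_counts_under_dropout(self):
        """Decoder means should be closer to the generative NB means than the
        dropout-corrupted observed counts are."""
        wins = []
        for seed in range(3):
            spec = SyntheticSpec(n_cells=200, n_genes=100, n_peaks=120,
                                 dropout_pi=0.4, seed=seed)
            data, _, gt = generate_paired_dataset(spec, return_params=True)
            cfg = ModelConfig(pretrain_epochs=40, joint_epochs=60, seed=seed)
            state, _, _ = train(data, cfg)
            m_r, _ = impute(state, data)
            mae_model = np.abs(m_r - gt["rna_mean"]).mean()
            mae_raw = np.abs(data.rna_counts - gt["rna_mean"]).mean()
            wins.append(mae_model < mae_raw)
        assert all(wins)
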