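"""Architecture contracts: masking, nonnegativity, seeding, sampling."""

import copy

import numpy as np
import pytest

from gmvae import (
    EncoderSpec,
    GeneModule,
    GeneModuleCollection,
    GeneModuleVAE,
    LatentLayout,
    LatentPosterior,
    build_mask,
    init_model,
    sample_latent,
)


@pytest.fixture(scope="module")
def tiny_mask():
    genes = [f"g{i}" for i in range(12)]
    coll = GeneModuleCollection(
        [
            GeneModule("m0", "", frozenset(genes[:5])),
            GeneModule("m1", "", frozenset(genes[4:9])),
            GeneModule("m2", "", frozenset(genes[8:])),
        ]
    )
    return build_mask(coll, genes, n_fc=1, min_genes=2)


def tiny_model(tiny_mask, seed=0, **kw):
    kw.setdefault("encoder_spec", EncoderSpec(n_hidden=8, seed=seed))
    return init_model(tiny_mask, **kw)


class TestInit:
    def test_latent_dim_and_decoder_shape(self, tiny_mask):
        m = tiny_model(tiny_mask)
        assert m.n_latent == 4
        assert m.params["theta"].shape == (12, 4)

    def test_same_seed_bitwise_identical(self, tiny_mask):
        a = tiny_model(tiny_mask, seed=7)
        b = tiny_model(tiny_mask, seed=7)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_fraction_at_least_mask_zero_fraction(self, rng):
        genes = [f"g{i}" for i in range(100)]
        mods = [
            GeneModule(f"m{j}", "", frozenset(rng.choice(genes, 15, replace=False)))
            for j in range(10)
        ]
        mm = build_mask(GeneModuleCollection(mods), genes, min_genes=1)
        m = init_model(mm, encoder_spec=EncoderSpec(n_hidden=8, seed=0))
        frac_mask_zero = 1 - mm.mask.mean()
        frac_theta_zero = (m.params["theta"] == 0).mean()
        assert frac_theta_zero >= frac_mask_zero
        # masked entries are exactly zero at init
        assert (m.params["theta"][mm.mask == 0] == 0).all()

    def test_layout_mask_mismatch_rejected(self, tiny_mask):
        bad = LatentLayout(n_gmv=2, n_fc=1, n_covariate=0,
                           covariate_levels=[], latent_names=["a", "b", "c"])
        with pytest.raises(ValueError):
            GeneModuleVAE(tiny_mask, layout=bad)


class TestEncode:
    def test_constant_input_untrained_is_finite(self, tiny_mask):
        m = tiny_model(tiny_mask)
        X = np.full((5, 12), 3.0)
        post = m.encode(X)
        assert np.isfinite(post.mu).all() and np.isfinite(post.sigma).all()
        assert (post.sigma > 0).all()

    def test_eval_mode_is_deterministic(self, tiny_mask):
        m = tiny_model(tiny_mask)
        X = np.random.default_rng(0).normal(size=(6, 12))
        a, b = m.encode(X), m.encode(X)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_gene_count_mismatch_names_expected(self, tiny_mask):
        m = tiny_model(tiny_mask)
        with pytest.raises(ValueError, match="12"):
            m.encode(np.zeros((3, 9)))

    def test_trained_gmv_tracks_planted_activity(self, trained_null):
        adata, _, truth, model, _ = trained_null
        post = model.encode(np.asarray(adata.X))
        cols = model.mask.columns_of("gmv")
        rs = [
            abs(np.corrcoef(post.mu[:, c], truth.activities.iloc[:, j])[0, 1])
            for j, c in enumerate(cols)
        ]
        assert np.median(rs) >= 0.7


class TestSampleLatent:
    def test_sigma_zero_limit_returns_mu(self):
        mu = np.arange(6, dtype=float).reshape(2, 3)
        post = LatentPosterior(mu, np.full((2, 3), 1e-300))
        z = sample_latent(post, seed=0)
        np.testing.assert_allclose(z, mu, atol=1e-290)

    def test_moments_match_posterior(self):
        mu = np.array([[1.0, -2.0]])
        sigma = np.array([[0.5, 2.0]])
        post = LatentPosterior(np.repeat(mu, 10_000, 0), np.repeat(sigma, 10_000, 0))
        z = sample_latent(post, seed=1)
        assert (np.abs(z.mean(0) - mu[0]) <= 4 * sigma[0] / 100).all()
        # chi-square bound on the sample variance of 10^4 normal draws
        np.testing.assert_allclose(z.var(0), sigma[0] ** 2, rtol=0.06)

    def test_seeded_reproducibility(self):
        post = LatentPosterior(np.zeros((4, 3)), np.ones((4, 3)))
        np.testing.assert_array_equal(sample_latent(post, 9), sample_latent(post, 9))


class TestDecode:
    def test_zero_latent_no_bias_gives_zero(self, tiny_mask):
        m = tiny_model(tiny_mask, use_bias=False)
        np.testing.assert_array_equal(m.decode(np.zeros((3, 4))), np.zeros((3, 12)))

    def test_perturbing_one_node_touches_only_its_genes(self, tiny_mask):
        m = tiny_model(tiny_mask)
        z = np.zeros((1, 4))
        base = m.decode(z)
        z2 = z.copy()
        z2[0, 1] = 2.0
        delta = m.decode(z2) - base
        outside = tiny_mask.mask[:, 1] == 0
        np.testing.assert_array_equal(delta[0, outside], 0.0)

    def test_monotone_in_z_with_nonnegative_weights(self, tiny_mask):
        m = tiny_model(tiny_mask)
        grid = np.linspace(-3, 3, 13)
        for j in range(4):
            Z = np.zeros((13, 4))
            Z[:, j] = grid
            X = m.decode(Z)
            diffs = np.diff(X, axis=0)
            assert (diffs >= -1e-12).all()


class TestConstrain:
    def test_negative_unmasked_entry_clamped(self, tiny_mask):
        m = tiny_model(tiny_mask)
        i = np.argwhere(tiny_mask.mask == 1)[0]
        m.params["theta"][tuple(i)] = -0.3
        m.constrain()
        assert m.params["theta"][tuple(i)] == 0.0

    def test_idempotent(self, tiny_mask):
        m = tiny_model(tiny_mask)
        m.params["theta"] += np.random.default_rng(0).normal(size=(12, 4))
        m.constrain()
        once = m.params["theta"].copy()
        m.constrain()
        np.testing.assert_array_equal(once, m.params["theta"])

    def test_invariants_after_training(self, trained_null):
        _, _, _, model, _ = trained_null
        theta = model.params["theta"]
        assert np.abs(theta[model.mask.mask == 0]).max() == 0.0
        assert theta.min() >= 0.0


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_mask):
        """The hand-written backward pass agrees with central differences."""
        m = tiny_model(
            tiny_mask,
            encoder_spec=EncoderSpec(n_hidden=6, dropout_rate=0.0, seed=3),
            latent_dropout_rate=0.0,
        )
        X = np.random.default_rng(1).normal(size=(5, 12))

        def loss():
            rng = np.random.default_rng(42)
            recon, kl, _ = m.loss_and_grads(X, None, rng, kl_weight=0.7)
            return recon + 0.7 * kl

        recon, kl, grads = m.loss_and_grads(
            X, None, np.random.default_rng(42), kl_weight=0.7
        )
        h = 1e-6
        for k, P in m.params.items():
            flat_idx = np.linspace(0, P.size - 1, min(10, P.size)).astype(int)
            for fi in flat_idx:
                ij = np.unravel_index(fi, P.shape)
                old = P[ij]
                P[ij] = old + h
                lp = loss()
                P[ij] = old - h
                lm = loss()
                P[ij] = old
                fd = (lp - lm) / (2 * h)
                assert abs(fd - grads[k][ij]) < 1e-6, f"{k}[{ij}]"


class TestPersistence:
    def test_save_load_round_trip(self, trained_null, tmp_path):
        adata, _, _, model, _ = trained_null
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = GeneModuleVAE.load(path)
        X = np.asarray(adata.X)[:20]
        a, b = model.encode(X), back.encode(X)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        assert back.gmv_names == model.gmv_names


def test_fc_warning_above_sixteen(caplog):
    import logging

    genes = [f"g{i}" for i in range(30)]
    coll = GeneModuleCollection([GeneModule("m", "", frozenset(genes[:6]))])
    mm = build_mask(coll, genes, n_fc=17, min_genes=2)
    with caplog.at_level(logging.WARNING, logger="gmvae.model"):
        LatentLayout.from_mask(mm)
    assert any("n_fc=17" in r.message for r in caplog.records)
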