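import numpy as np
import pytest

from scdrp.model import (
    Adam,
    ArchitectureConfig,
    LatentEmbedding,
    ModelParameters,
    bce_loss,
    classify,
    decode,
    encode,
    loss_diff,
    loss_recon,
    sparse_decode,
    total_losses,
)
from scdrp._autodiff import Tensor


def toy_params(rng, n_genes=6, ds=4, dp=3, hidden=5, mode="share_ae_pathways",
               mask=None, dropout=0.0, r1=0.1, r2=0.1):
    if mode == "share_ae_pathways" and mask is None:
        mask = (rng.random((ds, n_genes)) < 0.5).astype(float)
        mask[-1] = 1.0  # one free row
    arch = ArchitectureConfig(
        n_genes=n_genes, latent_dim_shared=ds, latent_dim_private=dp,
        hidden_dim=hidden, dropout=dropout, r1=r1, r2=r2,
        classifier_hidden=(4, 3), mode=mode,
    )
    return ModelParameters.init(arch, rng, mask=mask)


def np_two_layer(x, l1, l2):
    h = np.maximum(x @ l1.W.value + l1.b.value, 0.0)
    return h @ l2.W.value + l2.b.value


class TestForwardOracles:
    """Each forward op must match an explicit dense-algebra computation."""

    @pytest.mark.parametrize("seed", range(10))
    def test_encode_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = toy_params(rng)
        x = rng.normal(size=(7, 6))
        for domain, enc in (("bulk", p.private_encoder_bulk), ("sc", p.private_encoder_sc)):
            z = encode(x, p, domain)
            np.testing.assert_allclose(
                z.shared, np_two_layer(x, *p.shared_encoder), atol=1e-6
            )
            np.testing.assert_allclose(z.private, np_two_layer(x, *enc), atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_decode_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = toy_params(rng)
        z = encode(rng.normal(size=(4, 6)), p, "bulk")
        out = decode(z, p)
        latent = np.concatenate([z.private, z.shared], axis=1)
        np.testing.assert_allclose(
            out.value, np_two_layer(latent, *p.decoder), atol=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_sparse_decode_matches_masked_product(self, seed):
        rng = np.random.default_rng(seed)
        p = toy_params(rng)
        z = rng.normal(size=(5, 4))
        out = sparse_decode(z, p)
        expected = np.maximum(
            z @ (p.sparse_W.value * p.mask) + p.sparse_b.value, 0.0
        )
        np.testing.assert_allclose(out.value, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_classify_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = toy_params(rng)
        z = rng.normal(size=(6, 4))
        l1, l2, l3 = p.classifier
        h = np.maximum(z @ l1.W.value + l1.b.value, 0)
        h = np.maximum(h @ l2.W.value + l2.b.value, 0)
        expected = 1 / (1 + np.exp(-(h @ l3.W.value + l3.b.value)))
        np.testing.assert_allclose(classify(z, p).value, expected, atol=1e-6)

    def test_zero_weights_give_zero_embedding(self, rng):
        p = toy_params(rng)
        for grp in (p.shared_encoder, p.private_encoder_bulk, p.private_encoder_sc):
            for lin in grp:
                lin.W.value[:] = 0
                lin.b.value[:] = 0
        z = encode(rng.normal(size=(3, 6)), p, "bulk")
        assert (z.shared == 0).all() and (z.private == 0).all()

    def test_hand_arithmetic_one_dim(self):
        # x=3 through W1=[1], b1=0, ReLU, W2=[2], b2=1  ->  7
        rng = np.random.default_rng(0)
        arch = ArchitectureConfig(n_genes=1, latent_dim_shared=1, latent_dim_private=1,
                                  hidden_dim=1, dropout=0.0, mode="share_ae")
        p = ModelParameters.init(arch, rng)
        p.shared_encoder[0].W.value[:] = 1.0
        p.shared_encoder[0].b.value[:] = 0.0
        p.shared_encoder[1].W.value[:] = 2.0
        p.shared_encoder[1].b.value[:] = 1.0
        z = encode(np.array([[3.0]]), p, "bulk")
        assert z.shared[0, 0] == pytest.approx(7.0)

    def test_sparse_masking_confines_contributions(self, rng):
        # a pathway dimension may only touch its member genes
        mask = np.zeros((3, 5))
        mask[0, [1, 2]] = 1  # pathway P touches g1, g2 only
        mask[1, :] = 1
        mask[2, :] = 1
        p = toy_params(rng, n_genes=5, ds=3, mask=mask)
        p.sparse_b.value[:] = 0.0
        z = np.array([[1.0, 0.0, 0.0]])  # indicator of P's dimension
        out = sparse_decode(z, p).value[0]
        assert (out[[0, 3, 4]] == 0).all()

    def test_classify_zero_params_gives_half(self, rng):
        p = toy_params(rng)
        for lin in p.classifier:
            lin.W.value[:] = 0
            lin.b.value[:] = 0
        np.testing.assert_allclose(
            classify(rng.normal(size=(4, 4)), p).value, 0.5
        )

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        p = toy_params(rng)
        out = classify(rng.normal(size=(50, 4)), p).value
        assert ((out > 0) & (out < 1)).all()


class TestLosses:
    def test_recon_perfect_is_zero(self, rng):
        x = rng.normal(size=(3, 4))
        assert loss_recon(x, x, Tensor(x), Tensor(x)).value == 0

    def test_recon_single_element(self):
        x1 = np.array([[1.0]])
        assert loss_recon(x1, x1, Tensor([[3.0]]), Tensor(x1)).value == pytest.approx(4.0)

    def test_recon_matches_mean_square_oracle(self, rng):
        xs, xb = rng.normal(size=(4, 5)), rng.normal(size=(3, 5))
        hs, hb = rng.normal(size=(4, 5)), rng.normal(size=(3, 5))
        got = loss_recon(xs, xb, Tensor(hs), Tensor(hb)).value
        assert got == pytest.approx(((xs - hs) ** 2).mean() + ((xb - hb) ** 2).mean())

    def test_diff_single_sample_hand_case(self):
        # one sample, z_p = z_s = [1, 0]  ->  cross [[1,0],[0,0]], loss 1 per domain
        z = LatentEmbedding(Tensor(np.array([[1.0, 0.0]])),
                            Tensor(np.array([[1.0, 0.0]])), "sc")
        zb = LatentEmbedding(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 2))), "bulk")
        assert loss_diff(z, zb).value == pytest.approx(1.0)

    def test_diff_zero_for_orthogonal_centered_embeddings(self):
        # columns orthogonal, zero-mean, equal row norms -> penalty exactly 0
        from scipy.linalg import hadamard

        h = hadamard(8).astype(float)
        zp, zs = h[:, [1, 2]], h[:, [4, 5]]
        assert zp.T @ zs == pytest.approx(np.zeros((2, 2)))
        z_sc = LatentEmbedding(Tensor(zp), Tensor(zs), "sc")
        z_bk = LatentEmbedding(Tensor(zp.copy()), Tensor(zs.copy()), "bulk")
        assert loss_diff(z_sc, z_bk).value == pytest.approx(0.0, abs=1e-12)

    def test_diff_scale_invariance(self, rng):
        # row-normalization makes the penalty invariant to embedding scale
        zp, zs = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        a = loss_diff(
            LatentEmbedding(Tensor(zp), Tensor(zs), "sc"),
            LatentEmbedding(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3))), "bulk"),
        ).value
        b = loss_diff(
            LatentEmbedding(Tensor(zp * 100), Tensor(zs * 0.01), "sc"),
            LatentEmbedding(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3))), "bulk"),
        ).value
        assert a == pytest.approx(b, rel=1e-9)

    def test_total_losses_composition(self, rng):
        p = toy_params(rng, r1=0.1, r2=0.1)
        xb, xs = rng.normal(size=(5, 6)), rng.normal(size=(4, 6))
        out = total_losses(xb, xs, p)
        assert out["ae"].value == pytest.approx(
            out["recon"].value + 0.1 * out["diff"].value, abs=1e-9
        )
        assert out["train"].value == pytest.approx(
            out["ae"].value + 0.1 * out["sparse"].value, abs=1e-9
        )

    def test_degenerate_weights_reduce_to_recon(self, rng):
        p = toy_params(rng, r1=0.0, r2=0.0)
        xb, xs = rng.normal(size=(5, 6)), rng.normal(size=(4, 6))
        out = total_losses(xb, xs, p)
        assert out["train"].value == pytest.approx(out["recon"].value)

    def test_all_losses_non_negative(self, rng):
        p = toy_params(rng)
        out = total_losses(rng.normal(size=(5, 6)), rng.normal(size=(4, 6)), p)
        for key in ("recon", "diff", "sparse", "ae", "train"):
            assert out[key].value >= 0
        assert out["train"].value >= out["recon"].value

    def test_bce_closed_forms(self):
        assert bce_loss([1, 0], [0.5, 0.5]).value == pytest.approx(np.log(2))
        assert bce_loss([1], [1 - 1e-7]).value == pytest.approx(0.0, abs=1e-6)

    def test_bce_matches_literal_formula(self, rng):
        y = (rng.random(100) < 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, size=100)
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bce_loss(y, p).value == pytest.approx(expected, abs=1e-9)

    def test_bce_clamps_extreme_probabilities(self):
        assert np.isfinite(bce_loss([1.0], [0.0]).value)

    def test_bce_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError, match="length mismatch"):
            bce_loss([1, 0], [0.5])


class TestParameterBookkeeping:
    def test_mask_zero_positions_stay_zero_through_adam(self, rng):
        p = toy_params(rng)
        opt = Adam(p.autoencoder_parameters(), lr=1e-2)
        xb, xs = rng.normal(size=(8, 6)), rng.normal(size=(8, 6))
        for _ in range(25):
            out = total_losses(xb, xs, p, train=True, rng=rng)
            opt.zero_grad()
            out["train"].backward()
            opt.step()
            p.apply_mask()
        assert (p.sparse_W.value[p.mask == 0] == 0).all()

    def test_shared_encoder_is_one_object(self, rng):
        # a bulk-driven update must change the sc-side shared embedding
        p = toy_params(rng)
        x_sc = rng.normal(size=(3, 6))
        before = encode(x_sc, p, "sc").shared.copy()
        opt = Adam([t for lin in p.shared_encoder for t in (lin.W, lin.b)], lr=0.05)
        xb = rng.normal(size=(4, 6))
        z = encode(xb, p, "bulk")
        loss = z.z_shared.square().mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = encode(x_sc, p, "sc").shared
        assert not np.allclose(before, after)

    def test_private_encoders_are_domain_isolated(self, rng):
        p = toy_params(rng)
        x = rng.normal(size=(3, 6))
        before = encode(x, p, "sc").private.copy()
        for lin in p.private_encoder_bulk:
            lin.W.value += 1.0
        np.testing.assert_array_equal(encode(x, p, "sc").private, before)

    def test_save_load_round_trip(self, tmp_path, rng):
        p = toy_params(rng)
        p.save(tmp_path / "ckpt")
        q = ModelParameters.load(tmp_path / "ckpt")
        x = rng.normal(size=(4, 6))
        np.testing.assert_array_equal(
            encode(x, p, "bulk").shared, encode(x, q, "bulk").shared
        )
        np.testing.assert_array_equal(
            classify(encode(x, p, "sc").shared, p).value,
            classify(encode(x, q, "sc").shared, q).value,
        )
        np.testing.assert_array_equal(p.mask, q.mask)

    def test_dimension_mismatch_raises(self, rng):
        p = toy_params(rng)
        with pytest.raises(ValueError, match="genes"):
            encode(rng.normal(size=(3, 5)), p, "bulk")
        with pytest.raises(ValueError, match="mask row count"):
            sparse_decode(rng.normal(size=(3, 7)), p)
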