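"""Architecture: attention-pool equation oracle, variants, persistence, pretraining."""

import numpy as np
import pytest

from attnmpi import featurize as fz
from attnmpi.model import (InteractionModel, MaskedLM, ModelConfig, VARIANTS,
                           masked_accuracy, masked_pretrain)
from attnmpi.nn import Tensor


def tiny_config(**kw):
    base = dict(d_embed=8, n_transformer_layers=1, transformer_heads=2,
                ff_dim=16, attention_space=4, n_heads=2, n_residual_blocks=1,
                hidden_dim=16, met_hidden=12, dropout=0.0, seq_len=6,
                dtype="float64")
    base.update(kw)
    return ModelConfig(**base)


def attention_pool_oracle(pool, met_emb, prot_mat, theta_scale, S, M):
    """Straight-line re-implementation of the pooling equations, one head and
    one sample at a time: project with phi_met/phi_prot, scaled dot-product,
    softmax, weighted pooling, per-head linear map, concatenation."""
    B, N, d = prot_mat.shape
    denom = np.sqrt(N) if theta_scale == "sqrt_n" else np.sqrt(S)
    outs = np.zeros((B, M * (S // M)))
    alphas = np.zeros((M, B, N))
    for h in range(M):
        Wm1, bm1 = pool.Wm1.data[h], pool.bm1.data[h, 0]
        Wm2, bm2 = pool.Wm2.data[h], pool.bm2.data[h, 0]
        Wp1, bp1 = pool.Wp1.data[h, 0], pool.bp1.data[h, 0, 0]
        Wp2, bp2 = pool.Wp2.data[h, 0], pool.bp2.data[h, 0, 0]
        Wh, bh = pool.Wh.data[h], pool.bh.data[h, 0]
        for b in range(B):
            h_met = np.maximum(met_emb[b] @ Wm1 + bm1, 0) @ Wm2 + bm2
            h_prot = np.stack([
                np.maximum(prot_mat[b, k] @ Wp1 + bp1, 0) @ Wp2 + bp2
                for k in range(N)])
            theta = np.array([h_met @ h_prot[k] for k in range(N)]) / denom
            e = np.exp(theta - theta.max())
            alpha = e / e.sum()
            z = sum(alpha[k] * h_prot[k] for k in range(N))
            outs[b, h * (S // M):(h + 1) * (S // M)] = z @ Wh + bh
            alphas[h, b] = alpha
    return outs, alphas


class TestAttentionPool:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_equation_oracle(self, seed):
        # N=6, S=4, M=2 as the canonical small instance
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=seed)
        rng = np.random.default_rng(seed)
        met_emb = rng.normal(size=(3, cfg.d_embed))
        prot = rng.normal(size=(3, cfg.seq_len, cfg.d_embed))
        pooled, alphas = model.pool(Tensor(met_emb), Tensor(prot))
        exp_pool, exp_alpha = attention_pool_oracle(
            model.pool, met_emb, prot, cfg.theta_scale,
            cfg.attention_space, cfg.n_heads)
        np.testing.assert_allclose(pooled.detach(), exp_pool, atol=1e-5)
        np.testing.assert_allclose(alphas, exp_alpha, atol=1e-5)

    def test_constant_theta_gives_uniform_attention_and_mean_pooling(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        # identical phi_prot output for every position -> alpha uniform
        rng = np.random.default_rng(0)
        row = rng.normal(size=cfg.d_embed)
        prot = np.tile(row, (2, cfg.seq_len, 1))
        met = rng.normal(size=(2, cfg.d_embed))
        _, alphas = model.pool(Tensor(met), Tensor(prot))
        np.testing.assert_allclose(alphas, 1.0 / cfg.seq_len, atol=1e-12)

    def test_alpha_sums_to_one(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=1)
        rng = np.random.default_rng(3)
        _, alphas = model.pool(Tensor(rng.normal(size=(4, cfg.d_embed))),
                               Tensor(rng.normal(size=(4, cfg.seq_len, cfg.d_embed))))
        np.testing.assert_allclose(alphas.sum(axis=-1), 1.0, atol=1e-5)
        assert (alphas >= 0).all()

    def test_alpha_permutation_equivariance(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=2)
        rng = np.random.default_rng(4)
        met = rng.normal(size=(1, cfg.d_embed))
        prot = rng.normal(size=(1, cfg.seq_len, cfg.d_embed))
        perm = rng.permutation(cfg.seq_len)
        _, a = model.pool(Tensor(met), Tensor(prot))
        _, a_perm = model.pool(Tensor(met), Tensor(prot[:, perm]))
        np.testing.assert_allclose(a_perm, a[:, :, perm], atol=1e-10)

    def test_s_less_than_m_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(attention_space=1, n_heads=2)


class TestEncoders:
    def test_zero_gates_make_encoder_identity(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        x = np.random.default_rng(0).normal(size=(2, cfg.seq_len, cfg.d_embed))
        out = model.encoder(Tensor(x)).detach()
        np.testing.assert_array_equal(out, x)

    def test_encoder_shape_and_determinism(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        for p in model.encoder.parameters():
            if p.data.size == 1:
                p.data[:] = 0.7
        x = np.random.default_rng(1).normal(size=(3, cfg.seq_len, cfg.d_embed))
        a = model.encoder(Tensor(x)).detach()
        b = model.encoder(Tensor(x)).detach()
        assert a.shape == x.shape
        np.testing.assert_array_equal(a, b)

    def test_encoder_rejects_wrong_width(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        with pytest.raises(ValueError):
            model.encoder(Tensor(np.zeros((1, cfg.seq_len, cfg.d_embed + 1))))

    def test_metabolite_embedding_width_and_determinism(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=7, seed=0)
        x = np.random.default_rng(0).normal(size=(4, 7))
        e1 = model.met_encoder(Tensor(x), train=False).detach()
        e2 = model.met_encoder(Tensor(x), train=False).detach()
        assert e1.shape == (4, cfg.d_embed)
        np.testing.assert_array_equal(e1, e2)


class TestForward:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_output_probabilities(self, variant):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0, variant=variant)
        rng = np.random.default_rng(0)
        p = model.predict_proba(rng.normal(size=(3, 5)),
                                rng.normal(size=(3, cfg.seq_len, cfg.d_embed)))
        assert p.shape == (3,)
        assert ((p > 0) & (p < 1)).all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            InteractionModel(tiny_config(), met_input_dim=5, variant="bogus")

    def test_nt_avp_equals_mean_pool_oracle(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0, variant="NT+AvP")
        rng = np.random.default_rng(1)
        met = rng.normal(size=(2, 5))
        prot = rng.normal(size=(2, cfg.seq_len, cfg.d_embed))
        got = model.forward_logits(met, prot, train=False).detach()
        # oracle: mean over positions, concatenated with the metabolite
        # embedding, through the head
        from attnmpi.nn import concat

        me = model.met_encoder(Tensor(met), train=False)
        pooled = Tensor(prot.mean(axis=1))
        expect = model.head(concat([pooled, me], axis=-1), train=False).detach()
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_zero_final_layer_gives_half(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        model.head.out.W.data[:] = 0.0
        model.head.out.b.data[:] = 0.0
        rng = np.random.default_rng(0)
        p = model.predict_proba(rng.normal(size=(2, 5)),
                                rng.normal(size=(2, cfg.seq_len, cfg.d_embed)))
        np.testing.assert_allclose(p, 0.5)

    def test_gradients_reach_every_parameter_group(self):
        from attnmpi.nn import bce_with_logits

        cfg = tiny_config(dropout=0.0)
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        for p in model.parameters():
            if p.data.size == 1:
                p.data[:] = 0.4  # open the residual gates
        rng = np.random.default_rng(0)
        logits = model.forward_logits(rng.normal(size=(6, 5)),
                                      rng.normal(size=(6, cfg.seq_len, cfg.d_embed)),
                                      train=True)
        loss = bce_with_logits(logits, np.array([1., 0., 1., 0., 1., 0.]))
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.abs(p.grad).max() > 0 or p.data.size == 1

    def test_feature_width_mismatch_rejected(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        with pytest.raises(ValueError):
            model.forward_logits(np.zeros((1, 6)),
                                 np.zeros((1, cfg.seq_len, cfg.d_embed)))


class TestAttentionMaps:
    def test_maps_shape_and_normalization(self):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        rng = np.random.default_rng(0)
        maps = model.attention_maps(rng.normal(size=5),
                                    rng.normal(size=(cfg.seq_len, cfg.d_embed)),
                                    "m1", "p1")
        assert len(maps) == cfg.n_heads
        for am in maps:
            assert am.alpha.shape == (cfg.seq_len,)
            assert am.alpha.sum() == pytest.approx(1.0, abs=1e-5)

    def test_avp_variant_has_no_maps(self):
        model = InteractionModel(tiny_config(), met_input_dim=5, variant="NT+AvP")
        with pytest.raises(ValueError):
            model.attention_maps(np.zeros(5), np.zeros((6, 8)))


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        rng = np.random.default_rng(0)
        met = rng.normal(size=(3, 5))
        prot = rng.normal(size=(3, cfg.seq_len, cfg.d_embed))
        before = model.predict_proba(met, prot)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = InteractionModel.load(path)
        np.testing.assert_array_equal(loaded.predict_proba(met, prot), before)

    def test_load_refuses_tampered_config(self, tmp_path):
        import json

        cfg = tiny_config()
        model = InteractionModel(cfg, met_input_dim=5, seed=0)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        blob = dict(np.load(path))
        meta = json.loads(bytes(blob["meta"].tobytes()).decode())
        meta["config"]["n_heads"] = 1  # tamper without updating the hash
        blob["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **blob)
        with pytest.raises(ValueError, match="hash"):
            InteractionModel.load(path)


class TestMaskedPretraining:
    def test_single_residue_corpus_reaches_perfect_accuracy(self):
        cfg = tiny_config(seq_len=16, d_embed=24, transformer_heads=2, ff_dim=32)
        table = fz.ResidueEmbeddingTable(n_features=24)
        corpus = [fz.tokenize_protein(f"p{i}", "A" * 10, pad_to=16)
                  for i in range(8)]
        mlm, history = masked_pretrain(corpus, table, cfg, epochs=120,
                                       lr=1e-2, seed=0)
        assert history[-1] < history[0]
        acc = masked_accuracy(mlm, corpus, table, seed=1)
        assert acc == 1.0

    def test_uniform_random_corpus_stays_near_chance(self):
        cfg = tiny_config(seq_len=16, d_embed=24, transformer_heads=2, ff_dim=32)
        table = fz.ResidueEmbeddingTable(n_features=24)
        rng = np.random.default_rng(0)
        corpus = [fz.tokenize_protein(
            f"p{i}", "".join(rng.choice(list(fz.AA_ALPHABET), 12)), pad_to=16)
            for i in range(20)]
        mlm, _ = masked_pretrain(corpus, table, cfg, epochs=3, lr=1e-3, seed=0)
        acc = masked_accuracy(mlm, corpus, table, mask_rate=0.3, seed=1)
        assert acc < 0.4  # 1/20 in expectation; generous bound

    def test_fixed_motif_is_reconstructed(self):
        # deterministic motif ACDE at a fixed offset in every sequence:
        # masked positions inside the motif become predictable
        cfg = tiny_config(seq_len=24, d_embed=24, ff_dim=48)
        table = fz.ResidueEmbeddingTable(n_features=24)
        rng = np.random.default_rng(5)
        corpus = []
        for i in range(24):
            seq = list(rng.choice(list("GHIKLMNP"), 16))
            seq[4:8] = list("ACDE")
            corpus.append(fz.tokenize_protein(f"p{i}", "".join(seq), pad_to=24))
        mlm, _ = masked_pretrain(corpus, table, cfg, mask_rate=0.25,
                                 epochs=60, batch_size=8, lr=3e-3, seed=0)
        toks = np.stack([tp.tokens for tp in corpus])
        motif_pos = np.zeros_like(toks, dtype=bool)
        motif_pos[:, 5:9] = True  # motif offset shifted by the BEGIN token
        acc = masked_accuracy(mlm, corpus, table, mask_rate=0.5, seed=2,
                              positions=motif_pos)
        assert acc > 0.9

    def test_invalid_mask_rate(self):
        cfg = tiny_config()
        table = fz.ResidueEmbeddingTable(n_features=24)
        corpus = [fz.tokenize_protein("p", "ACDE", pad_to=6)]
        with pytest.raises(ValueError):
            masked_pretrain(corpus, table, cfg, mask_rate=1.5)

    def test_pretrained_encoder_transfers(self):
        cfg = tiny_config(seq_len=16, d_embed=24, transformer_heads=2, ff_dim=32)
        table = fz.ResidueEmbeddingTable(n_features=24)
        corpus = [fz.tokenize_protein(f"p{i}", "ACDEGHIK", pad_to=16)
                  for i in range(4)]
        mlm, _ = masked_pretrain(corpus, table, cfg, epochs=2, seed=0)
        model = InteractionModel(cfg, met_input_dim=5, seed=1)
        model.load_encoder(mlm)
        src = list(mlm.encoder.parameters())[0].data
        dst = list(model.encoder.parameters())[0].data
        np.testing.assert_allclose(src, dst)
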