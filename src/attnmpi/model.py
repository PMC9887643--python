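"""The metabolite-protein interaction model.

Four stages compose the full architecture:

1. **Protein encoder** — a stack of transformer encoder layers, each wrapped in
   a learnable residual connection ``x + gate * layer(x)`` with the scalar gate
   initialized at zero, applied to the position-encoded residue embeddings.
2. **Compound encoder** — batch normalization followed by linear layers with
   rectifier activations, mapping the processed metabolite feature vector to a
   128-dimensional embedding.
3. **Cross-attention pooling** — for each of M heads, the metabolite embedding
   and every residue's contextual embedding are projected into a common
   attention space of size S by two-layer perceptrons (phi_met, phi_prot); the
   scaled dot product theta_k = <H_met, H_prot_k> / sqrt(N) is softmax-normalized
   into attention weights alpha over the N sequence positions (padding
   included — no masking), the residue projections are pooled as
   Z = sum_k alpha_k H_prot_k, and a per-head linear map phi_head takes Z from
   S down to S // M before the heads are concatenated.
4. **Prediction head** — the pooled features concatenated with the metabolite
   embedding pass through fully-connected residual blocks and a final linear
   map; a sigmoid yields the interaction probability.

Simplified variants replace the transformer stack by the identity (NT) and/or
attention pooling by unweighted average pooling (AvP); a logistic-regression
variant maps [mean-pooled residue embeddings || metabolite features] linearly
to the probability. The transformer stack can be pretrained by masked-residue
prediction before supervised training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import featurize
from .nn import (Adam, BatchNorm1d, Dropout, GatedResidual, Linear, Module,
                 Tensor, TransformerLayer, concat, softmax_cross_entropy)

__all__ = [
    "ModelConfig",
    "InteractionModel",
    "AttentionMap",
    "VARIANTS",
    "MaskedLM",
    "masked_pretrain",
    "masked_accuracy",
]

VARIANTS = ("T+AttP", "T+AvP", "NT+AttP", "NT+AvP", "logistic")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``n_heads`` (M) defaults to 16, the value tied to the pooling equations;
    ``attention_space`` (S) defaults to the embedding width. ``theta_scale``
    selects the denominator of the scaled dot product: "sqrt_n" divides by the
    square root of the padded sequence length N (the definitional choice here),
    "sqrt_s" by the square root of the attention space size.
    """

    d_embed: int = 128
    n_transformer_layers: int = 3
    transformer_heads: int = 8
    ff_dim: int | None = None          # transformer feed-forward width; 4*d_embed if None
    attention_space: int = 128         # S
    n_heads: int = 16                  # M
    n_residual_blocks: int = 5
    hidden_dim: int = 2048
    met_hidden: int = 512
    dropout: float = 0.33
    seq_len: int = 1024                # N (padded token count)
    theta_scale: str = "sqrt_n"
    self_attn_pad_mask: bool = False
    dtype: str = "float64"

    def __post_init__(self):
        if self.ff_dim is None:
            self.ff_dim = 4 * self.d_embed
        if self.attention_space // self.n_heads < 1:
            raise ValueError("attention_space // n_heads must be >= 1")
        if self.theta_scale not in ("sqrt_n", "sqrt_s"):
            raise ValueError(f"unknown theta_scale {self.theta_scale!r}")
        for name in ("d_embed", "n_transformer_layers", "transformer_heads",
                     "attention_space", "n_heads", "n_residual_blocks",
                     "hidden_dim", "met_hidden", "seq_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type

    @property
    def pooled_width(self) -> int:
        return self.n_heads * (self.attention_space // self.n_heads)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class AttentionMap:
    """One head's attention weights over the padded sequence for one pair."""

    head: int
    alpha: np.ndarray  # (seq_len,), non-negative, sums to 1
    metabolite_id: str = ""
    protein_id: str = ""


def _make_encoder(cfg: ModelConfig, rng) -> list:
    dt = cfg.np_dtype
    return [GatedResidual(TransformerLayer(cfg.d_embed, cfg.transformer_heads,
                                           cfg.ff_dim, rng, cfg.dropout, dtype=dt),
                          dtype=dt)
            for _ in range(cfg.n_transformer_layers)]


class ProteinEncoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.layers = [self.child(l) for l in _make_encoder(cfg, rng)]

    def __call__(self, x: Tensor, train: bool = False,
                 pad_mask: np.ndarray | None = None) -> Tensor:
        if x.shape[-1] != self.cfg.d_embed:
            raise ValueError(f"expected embedding width {self.cfg.d_embed}, "
                             f"got {x.shape[-1]}")
        for layer in self.layers:
            x = layer(x, train=train, pad_mask=pad_mask)
        return x


class MetaboliteEncoder(Module):
    """Batch norm + two linear layers with a rectifier, to a 128-d embedding."""

    def __init__(self, cfg: ModelConfig, met_input_dim: int, rng):
        super().__init__()
        dt = cfg.np_dtype
        self.bn = self.child(BatchNorm1d(met_input_dim, dtype=dt))
        self.fc1 = self.child(Linear(met_input_dim, cfg.met_hidden, rng, dtype=dt))
        self.fc2 = self.child(Linear(cfg.met_hidden, cfg.d_embed, rng, dtype=dt))
        self.drop = self.child(Dropout(cfg.dropout, rng))

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        h = self.bn(x, train=train)
        return self.fc2(self.drop(self.fc1(h).relu(), train=train))


class AttentionPool(Module):
    """Multi-head cross-attention pooling of the residue matrix, keyed on the
    metabolite embedding. Per head: phi_met/phi_prot (two linear layers with a
    rectifier, width d -> S), scaled dot-product similarities, softmax weights
    over all N positions (padding attended by design), weighted pooling, and a
    linear phi_head from S to S//M; heads are concatenated.
    """

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        M, S, d = cfg.n_heads, cfg.attention_space, cfg.d_embed
        dt = cfg.np_dtype
        k = 1.0 / np.sqrt(d)
        ks = 1.0 / np.sqrt(S)
        self.cfg = cfg
        self.Wm1 = self.param(rng.uniform(-k, k, (M, d, S)).astype(dt))
        self.bm1 = self.param(np.zeros((M, 1, S), dtype=dt))
        self.Wm2 = self.param(rng.uniform(-ks, ks, (M, S, S)).astype(dt))
        self.bm2 = self.param(np.zeros((M, 1, S), dtype=dt))
        self.Wp1 = self.param(rng.uniform(-k, k, (M, 1, d, S)).astype(dt))
        self.bp1 = self.param(np.zeros((M, 1, 1, S), dtype=dt))
        self.Wp2 = self.param(rng.uniform(-ks, ks, (M, 1, S, S)).astype(dt))
        self.bp2 = self.param(np.zeros((M, 1, 1, S), dtype=dt))
        self.Wh = self.param(rng.uniform(-ks, ks, (M, S, S // M)).astype(dt))
        self.bh = self.param(np.zeros((M, 1, S // M), dtype=dt))

    def __call__(self, met_emb: Tensor, prot_mat: Tensor):
        cfg = self.cfg
        B = met_emb.shape[0]
        N = prot_mat.shape[1]
        # H_met: (M, B, S); H_prot: (M, B, N, S)
        hm = ((met_emb.reshape(1, B, cfg.d_embed) @ self.Wm1 + self.bm1).relu()
              @ self.Wm2 + self.bm2)
        hp = ((prot_mat.reshape(1, B, N, cfg.d_embed) @ self.Wp1 + self.bp1).relu()
              @ self.Wp2 + self.bp2)
        denom = np.sqrt(N if cfg.theta_scale == "sqrt_n" else cfg.attention_space)
        theta = (hm.reshape(cfg.n_heads, B, 1, cfg.attention_space) * hp
                 ).sum(axis=-1) * (1.0 / denom)            # (M, B, N)
        alpha = theta.softmax(axis=-1)
        z = (alpha.reshape(cfg.n_heads, B, N, 1) * hp).sum(axis=2)  # (M, B, S)
        pooled = z @ self.Wh + self.bh                      # (M, B, S//M)
        out = pooled.transpose(1, 0, 2).reshape(B, cfg.pooled_width)
        return out, alpha.detach()


class PredictionHead(Module):
    """Residual fully-connected stack ending in a single logit."""

    def __init__(self, cfg: ModelConfig, in_dim: int, rng):
        super().__init__()
        dt = cfg.np_dtype
        self.proj = self.child(Linear(in_dim, cfg.hidden_dim, rng, dtype=dt))
        self.blocks = []
        for _ in range(cfg.n_residual_blocks):
            blk = (self.child(Linear(cfg.hidden_dim, cfg.hidden_dim, rng, dtype=dt)),
                   self.child(Linear(cfg.hidden_dim, cfg.hidden_dim, rng, dtype=dt)),
                   self.child(Dropout(cfg.dropout, rng)))
            self.blocks.append(blk)
        self.out = self.child(Linear(cfg.hidden_dim, 1, rng, dtype=dt))

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        h = self.proj(x).relu()
        for fc1, fc2, drop in self.blocks:
            h = h + drop(fc2(fc1(h).relu()), train=train)
        return self.out(h).reshape(-1)


class InteractionModel(Module):
    """Configuration plus learnable parameters of all four stages.

    ``variant`` selects the composition: "T+AttP" (the full model), "T+AvP",
    "NT+AttP", "NT+AvP" and "logistic". Forward maps (processed metabolite
    features, position-encoded residue matrix) to a probability in (0, 1).
    """

    def __init__(self, config: ModelConfig, met_input_dim: int,
                 seed: int = 0, variant: str = "T+AttP"):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.cfg = config
        self.variant = variant
        self.met_input_dim = met_input_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        if variant == "logistic":
            self.linear = self.child(
                Linear(config.d_embed + met_input_dim, 1, rng, dtype=dt))
            return
        self.use_transformer = variant.startswith("T")
        self.use_attention = variant.endswith("AttP")
        if self.use_transformer:
            self.encoder = self.child(ProteinEncoder(config, rng))
        self.met_encoder = self.child(MetaboliteEncoder(config, met_input_dim, rng))
        if self.use_attention:
            self.pool = self.child(AttentionPool(config, rng))
            head_in = config.pooled_width + config.d_embed
        else:
            head_in = 2 * config.d_embed
        self.head = self.child(PredictionHead(config, head_in, rng))

    # -- forward ------------------------------------------------------------

    def forward_logits(self, met_features: np.ndarray, prot_embedded: np.ndarray,
                       train: bool = False, return_attention: bool = False):
        """Logits for a batch; inputs are plain arrays (B, F) and (B, N, d)."""
        dt = self.cfg.np_dtype
        met = Tensor(np.asarray(met_features, dtype=dt))
        prot = Tensor(np.asarray(prot_embedded, dtype=dt))
        if met.ndim != 2 or prot.ndim != 3:
            raise ValueError("expected met (B, F) and prot (B, N, d)")
        if met.shape[1] != self.met_input_dim:
            raise ValueError(f"metabolite feature width {met.shape[1]} != "
                             f"fitted width {self.met_input_dim}")
        if self.variant == "logistic":
            pooled = prot.mean(axis=1)
            logits = self.linear(concat([pooled, met], axis=-1)).reshape(-1)
            return (logits, []) if return_attention else logits
        alphas = None
        if self.use_transformer:
            prot = self.encoder(prot, train=train)
        met_emb = self.met_encoder(met, train=train)
        if self.use_attention:
            pooled, alphas = self.pool(met_emb, prot)
        else:
            pooled = prot.mean(axis=1)
        logits = self.head(concat([pooled, met_emb], axis=-1), train=train)
        return (logits, alphas) if return_attention else logits

    def predict_proba(self, met_features, prot_embedded) -> np.ndarray:
        """Deterministic eval-mode interaction probabilities, strictly in (0, 1)."""
        logits = self.forward_logits(met_features, prot_embedded, train=False)
        return logits.sigmoid().detach()

    def attention_maps(self, met_features, prot_embedded,
                       metabolite_id: str = "", protein_id: str = "") -> list:
        """Per-head attention weights for a single pair."""
        if self.variant == "logistic" or not self.use_attention:
            raise ValueError(f"variant {self.variant!r} has no attention maps")
        met = np.atleast_2d(met_features)
        prot = np.asarray(prot_embedded)[None] if np.asarray(prot_embedded).ndim == 2 \
            else np.asarray(prot_embedded)
        _, alphas = self.forward_logits(met, prot, train=False, return_attention=True)
        return [AttentionMap(head=h, alpha=alphas[h, 0],
                             metabolite_id=metabolite_id, protein_id=protein_id)
                for h in range(alphas.shape[0])]

    # -- persistence ---------------------------------------------------------

    def _buffers(self):
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                yield m

    def save(self, path) -> None:
        """Checkpoint: config JSON + parameter/buffer blob, config-hashed."""
        meta = {"config": self.cfg.to_dict(), "config_hash": self.cfg.hash(),
                "variant": self.variant, "met_input_dim": self.met_input_dim,
                "seed": self.seed, "format_version": 1}
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._buffers()):
            arrays[f"bm{i}"] = bn.running_mean
            arrays[f"bv{i}"] = bn.running_var
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "InteractionModel":
        with np.load(path) as blob:
            meta = json.loads(bytes(blob["meta"].tobytes()).decode())
            cfg = ModelConfig(**meta["config"])
            if cfg.hash() != meta["config_hash"]:
                raise ValueError("checkpoint config hash mismatch")
            model = cls(cfg, meta["met_input_dim"], seed=meta["seed"],
                        variant=meta["variant"])
            model.load_state_arrays([blob[f"p{i}"]
                                     for i in range(len(list(model.parameters())))])
            for i, bn in enumerate(model._buffers()):
                bn.running_mean = blob[f"bm{i}"]
                bn.running_var = blob[f"bv{i}"]
        return model

    def load_encoder(self, pretrained: "MaskedLM") -> None:
        """Copy a masked-pretrained transformer stack into the protein encoder."""
        if not getattr(self, "use_transformer", False):
            raise ValueError("this variant has no transformer encoder")
        src = list(pretrained.encoder.parameters())
        dst = list(self.encoder.parameters())
        if len(src) != len(dst):
            raise ValueError("pretrained encoder does not match model config")
        for s, d in zip(src, dst):
            d.data = s.data.astype(d.data.dtype)


# --------------------------------------------------------------------------
# Masked pretraining
# --------------------------------------------------------------------------

N_RESIDUE_CLASSES = 21  # 20 amino acids + unknown


class MaskedLM(Module):
    """Transformer stack + linear head predicting the residue at masked positions."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = self.child(ProteinEncoder(cfg, rng))
        self.mask_vec = self.param(np.zeros(cfg.d_embed, dtype=cfg.np_dtype))
        self.out = self.child(Linear(cfg.d_embed, N_RESIDUE_CLASSES, rng,
                                     dtype=cfg.np_dtype))

    def logits(self, base_embed: np.ndarray, pe: np.ndarray,
               mask: np.ndarray, train: bool = False) -> Tensor:
        """``base_embed`` (B, N, d) token embeddings without positions, ``mask``
        (B, N) boolean; masked rows are replaced by the learned mask vector."""
        keep = (~mask)[..., None]
        x = Tensor(base_embed * keep + pe) + Tensor(mask[..., None].astype(
            self.cfg.np_dtype)) * self.mask_vec
        h = self.encoder(x, train=train)
        return self.out(h)


def _residue_positions(tokens: np.ndarray) -> np.ndarray:
    return tokens <= featurize.UNK


def masked_pretrain(tokenized: list, table: featurize.ResidueEmbeddingTable,
                    cfg: ModelConfig, mask_rate: float = 0.15, epochs: int = 5,
                    batch_size: int = 8, lr: float = 1e-3, seed: int = 0):
    """Train a transformer stack to reconstruct masked residues.

    Each step masks ``mask_rate`` of the residue positions (special tokens are
    never masked) and minimizes cross-entropy over the 21 residue classes at
    the masked positions. Returns (MaskedLM, per-epoch mean losses).
    """
    if not tokenized:
        raise ValueError("empty pretraining corpus")
    if not 0.0 < mask_rate < 1.0:
        raise ValueError(f"mask_rate must be in (0, 1), got {mask_rate}")
    dt = cfg.np_dtype
    toks = np.stack([tp.tokens for tp in tokenized])
    base = table.matrix[toks].astype(dt)
    pe = featurize.positional_encoding(toks.shape[1], table.n_features).astype(dt)
    residue = _residue_positions(toks)
    mlm = MaskedLM(cfg, seed=seed)
    opt = Adam(mlm.parameters(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(toks))
        losses = []
        for start in range(0, len(toks), batch_size):
            idx = order[start:start + batch_size]
            mask = residue[idx] & (rng.random(residue[idx].shape) < mask_rate)
            if not mask.any():
                continue
            logits = mlm.logits(base[idx], pe, mask, train=True)
            sel = logits[mask]
            targets = np.minimum(toks[idx][mask], featurize.UNK)
            loss = softmax_cross_entropy(sel, targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if not np.isfinite(history[-1]):
            raise RuntimeError("masked pretraining diverged (non-finite loss)")
    return mlm, history


def masked_accuracy(mlm: MaskedLM, tokenized: list,
                    table: featurize.ResidueEmbeddingTable,
                    mask_rate: float = 0.15, seed: int = 0,
                    positions: np.ndarray | None = None) -> float:
    """Reconstruction accuracy at masked positions (optionally restricted to a
    boolean per-sequence ``positions`` selector, e.g. motif offsets)."""
    dt = mlm.cfg.np_dtype
    toks = np.stack([tp.tokens for tp in tokenized])
    base = table.matrix[toks].astype(dt)
    pe = featurize.positional_encoding(toks.shape[1], table.n_features).astype(dt)
    candidates = _residue_positions(toks)
    if positions is not None:
        candidates = candidates & positions
    rng = np.random.default_rng(seed)
    mask = candidates & (rng.random(candidates.shape) < mask_rate)
    if not mask.any():
        raise ValueError("no positions selected for masking")
    logits = mlm.logits(base, pe, mask, train=False)
    pred = logits.detach().argmax(axis=-1)
    targets = np.minimum(toks, featurize.UNK)
    return float((pred[mask] == targets[mask]).mean())
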