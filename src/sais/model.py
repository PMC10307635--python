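"""Two-stream temporal transformer with prototype-contrastive classification.

A clip is summarised per modality by a transformer encoder over its frozen
per-frame embeddings: a learnable classification token is prepended, learned
temporal positional embeddings are added to the frame rows, and the token's
representation at the final encoder layer is the modality summary ``h_cls``.
The appearance and motion summaries are added elementwise (``h_agg = h_rgb +
h_flow``), projected through two linear layers with a ReLU to an E-dimensional
video embedding ``h_video``, and classified by cosine similarity to C learned
category prototypes followed by a softmax.  Training minimises an InfoNCE
objective whose logits are the raw cosine similarities (no temperature):
each video embedding is attracted to its own category's prototype and
repelled from the others.

Encoder parameters, the classification token and the positional embeddings
are shared across the two modality streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, layer_norm, softmax
from .features import APPEARANCE, MOTION, FrameFeatureSequence, VideoSample

__all__ = [
    "EncoderConfig",
    "PrototypeBank",
    "VideoEmbedding",
    "SAISNet",
    "aggregate",
    "classify",
    "info_nce_loss",
    "cosine_scores",
]

NEG_INF = -1e9


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters of the temporal encoder.

    ``use_self_attention=False`` (an ablation) replaces the encoder by a mean
    over valid frame vectors; ``modalities`` restricts the streams used (the
    single-modality ablations pass the missing summary as zero).
    """

    dim: int = 384                      # D: frozen frame-embedding dimension
    embed_dim: int = 256                # E: video-embedding / prototype dimension
    n_layers: int = 4
    n_heads: int = 8
    max_t: int = 512                    # positional-embedding capacity (frames)
    ffn_mult: int = 4
    dropout: float = 0.1
    use_self_attention: bool = True
    modalities: tuple[str, ...] = (APPEARANCE, MOTION)

    def __post_init__(self):
        if self.dim % self.n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        if self.n_layers < 1 or self.max_t < 1:
            raise ValueError("n_layers and max_t must be >= 1")
        if not set(self.modalities) <= {APPEARANCE, MOTION} or not self.modalities:
            raise ValueError("modalities must be a nonempty subset of appearance/motion")


@dataclass
class PrototypeBank:
    """C learnable E-dimensional category prototypes."""

    prototypes: np.ndarray
    category_names: list[str]

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, dtype=np.float64)
        if self.prototypes.ndim != 2 or self.prototypes.shape[0] < 2:
            raise ValueError("need a C x E matrix with C >= 2")
        if len(self.category_names) != self.prototypes.shape[0]:
            raise ValueError("one name per prototype required")
        norms = np.linalg.norm(self.prototypes, axis=1)
        if not np.all(np.isfinite(self.prototypes)) or np.any(norms == 0):
            raise ValueError("prototypes must be finite and nonzero")

    @property
    def n_categories(self) -> int:
        return self.prototypes.shape[0]


@dataclass(frozen=True)
class VideoEmbedding:
    """Intermediate summaries of one clip (h_agg = h_rgb + h_flow)."""

    h_rgb: np.ndarray
    h_flow: np.ndarray
    h_agg: np.ndarray
    h_video: np.ndarray


def _norm(x: Tensor, axis: int = -1) -> Tensor:
    return ((x * x).sum(axis=axis, keepdims=True) + 1e-30) ** 0.5


def cosine_scores(h: Tensor | np.ndarray, prototypes: Tensor | np.ndarray) -> Tensor:
    """Cosine similarity of each row of ``h`` (B, E) to each prototype (C, E).

    Norms are epsilon-stabilised: an exactly zero row (possible for an
    untrained projection head whose rectifier kills every unit) scores 0
    against every prototype instead of raising.
    """
    h = h if isinstance(h, Tensor) else Tensor(h)
    p = prototypes if isinstance(prototypes, Tensor) else Tensor(prototypes)
    hn = h / _norm(h)
    pn = p / _norm(p)
    return hn @ pn.swapaxes(-1, -2)


def aggregate(h_rgb: np.ndarray, h_flow: np.ndarray) -> np.ndarray:
    """Elementwise sum of the modality summaries (single-modality runs pass zero)."""
    h_rgb, h_flow = np.asarray(h_rgb), np.asarray(h_flow)
    if h_rgb.shape != h_flow.shape:
        raise ValueError(f"dimension mismatch: {h_rgb.shape} vs {h_flow.shape}")
    return h_rgb + h_flow


def classify(h_video: np.ndarray, bank: PrototypeBank) -> np.ndarray:
    """Probability mass over categories: softmax of cosine similarities.

    The predicted label is the argmax; ties break to the lowest category index.
    """
    h = np.atleast_2d(np.asarray(h_video, dtype=np.float64))
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite video embedding")
    if np.any(np.linalg.norm(h, axis=-1) == 0):
        raise ValueError("zero-norm video embedding has no cosine similarity")
    sims = cosine_scores(h, bank.prototypes).data
    e = np.exp(sims - sims.max(axis=-1, keepdims=True))
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs[0] if np.asarray(h_video).ndim == 1 else probs


def info_nce_loss(
    h_video: Tensor | np.ndarray,
    labels: np.ndarray,
    prototypes: Tensor | np.ndarray,
) -> Tensor:
    """Prototype InfoNCE: sum over the batch of -log softmax(cosine)[label].

    The exponent is the raw cosine similarity; there is no temperature.
    """
    h = h_video if isinstance(h_video, Tensor) else Tensor(h_video)
    labels = np.asarray(labels, dtype=np.int64)
    n_proto = (prototypes.data if isinstance(prototypes, Tensor) else np.asarray(prototypes)).shape[0]
    if labels.min() < 0 or labels.max() >= n_proto:
        raise ValueError("label without a matching prototype")
    sims = cosine_scores(h, prototypes)
    probs = softmax(sims, axis=-1)
    picked = probs[np.arange(len(labels)), labels]
    return -(picked.log().sum())


class SAISNet:
    """Parameters and forward passes of the two-stream prototype classifier.

    All parameters live in a flat ``name -> Tensor`` dict so stochastic
    gradient descent and serialization stay trivial.  The same encoder, token
    and positional embeddings serve both modality streams.
    """

    def __init__(self, config: EncoderConfig, categories: list[str], rng: np.random.Generator):
        if len(categories) < 2:
            raise ValueError("need at least two categories")
        self.config = config
        self.categories = list(categories)
        d, e, c = config.dim, config.embed_dim, len(categories)
        p: dict[str, Tensor] = {}

        def par(name, arr):
            p[name] = Tensor(arr, requires_grad=True)

        par("e_cls", rng.normal(0.0, 0.02, size=d))
        par("pos", rng.normal(0.0, 0.02, size=(config.max_t, d)))
        for l in range(config.n_layers):
            s = 1.0 / np.sqrt(d)
            for w in ("q", "k", "v", "o"):
                par(f"l{l}.W{w}", rng.normal(0.0, s, size=(d, d)))
                par(f"l{l}.b{w}", np.zeros(d))
            par(f"l{l}.ln1_g", np.ones(d))
            par(f"l{l}.ln1_b", np.zeros(d))
            par(f"l{l}.W1", rng.normal(0.0, s, size=(d, config.ffn_mult * d)))
            par(f"l{l}.b1", np.zeros(config.ffn_mult * d))
            par(f"l{l}.W2", rng.normal(0.0, 1.0 / np.sqrt(config.ffn_mult * d),
                                       size=(config.ffn_mult * d, d)))
            par(f"l{l}.b2", np.zeros(d))
            par(f"l{l}.ln2_g", np.ones(d))
            par(f"l{l}.ln2_b", np.zeros(d))
        par("proj_W1", rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, e)))
        par("proj_b1", np.zeros(e))
        par("proj_W2", rng.normal(0.0, 1.0 / np.sqrt(e), size=(e, e)))
        par("proj_b2", np.zeros(e))
        par("prototypes", rng.normal(0.0, 1.0, size=(c, e)))
        self.params = p
        self.last_cls_attention: np.ndarray | None = None

    # -- parameter bookkeeping ------------------------------------------------
    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def sgd_step(self, lr: float) -> None:
        for t in self.params.values():
            if t.grad is not None:
                t.data -= lr * t.grad

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    @property
    def prototype_bank(self) -> PrototypeBank:
        return PrototypeBank(self.params["prototypes"].data.copy(), self.categories)

    # -- forward passes -------------------------------------------------------
    def _dropout(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    def encode_modality(
        self,
        x: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture_attention: bool = False,
    ) -> Tensor:
        """Summarise padded frame sequences (B, T, D) into h_cls (B, D).

        Padded rows (mask False) are excluded from attention; with
        ``use_self_attention=False`` the summary is the mean of valid frames.
        """
        x = np.asarray(x, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        if x.ndim == 2:
            x, mask = x[None], mask[None]
        b, t, d = x.shape
        cfg = self.config
        if d != cfg.dim:
            raise ValueError(f"feature dim {d} != configured dim {cfg.dim}")
        if not cfg.use_self_attention:
            return self._encode_mean(x, mask)
        if t > cfg.max_t:
            raise ValueError(f"sequence length {t} exceeds positional capacity {cfg.max_t}")

        p = self.params
        frames = Tensor(x) + p["pos"][:t]
        # zero out padded rows so positional embeddings never leak through them
        frames = frames * Tensor(mask[..., None].astype(np.float64))
        cls_tok = p["e_cls"].reshape(1, 1, cfg.dim) * Tensor(np.ones((b, 1, 1)))
        h = concat([cls_tok, frames], axis=1)          # (B, T+1, D)
        full_mask = np.concatenate([np.ones((b, 1), dtype=bool), mask], axis=1)
        attn_bias = np.where(full_mask, 0.0, NEG_INF)[:, None, None, :]  # keys only

        n_heads, dh = cfg.n_heads, cfg.dim // cfg.n_heads
        scale = 1.0 / np.sqrt(dh)
        t1 = t + 1
        for l in range(cfg.n_layers):

            def heads(z):
                return z.reshape(b, t1, n_heads, dh).swapaxes(1, 2)  # (B,H,T1,dh)

            q = heads(h @ p[f"l{l}.Wq"] + p[f"l{l}.bq"])
            k = heads(h @ p[f"l{l}.Wk"] + p[f"l{l}.bk"])
            v = heads(h @ p[f"l{l}.Wv"] + p[f"l{l}.bv"])
            scores = (q @ k.swapaxes(-1, -2)) * scale + Tensor(attn_bias)
            weights = softmax(scores, axis=-1)          # (B,H,T1,T1)
            if capture_attention and l == cfg.n_layers - 1:
                self.last_cls_attention = weights.data[:, :, 0, 1:].copy()
            ctx = (weights @ v).swapaxes(1, 2).reshape(b, t1, cfg.dim)
            attn_out = self._dropout(ctx @ p[f"l{l}.Wo"] + p[f"l{l}.bo"], training, rng)
            h = layer_norm(h + attn_out, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            ffn = (h @ p[f"l{l}.W1"] + p[f"l{l}.b1"]).relu() @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
            h = layer_norm(h + self._dropout(ffn, training, rng), p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
        return h[:, 0, :]

    def _encode_mean(self, x: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean over valid frame vectors (self-attention ablation)."""
        x = np.asarray(x, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        w = mask.astype(np.float64)
        denom = np.maximum(w.sum(axis=1, keepdims=True), 1.0)
        return (Tensor(x) * Tensor(w[..., None])).sum(axis=1) * Tensor(1.0 / denom)

    def forward(
        self,
        x_app: np.ndarray,
        x_flow: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture_attention: bool = False,
    ) -> tuple[Tensor, dict[str, Tensor]]:
        """Full pass to h_video (B, E); returns intermediates for inspection."""
        cfg = self.config
        parts: dict[str, Tensor] = {}
        attn: dict[str, np.ndarray] = {}
        zero = Tensor(np.zeros((np.asarray(mask).shape[0], cfg.dim)))
        for modality, x in ((APPEARANCE, x_app), (MOTION, x_flow)):
            if modality in cfg.modalities and x is not None:
                if cfg.use_self_attention:
                    h = self.encode_modality(x, mask, training, rng, capture_attention)
                    if capture_attention:
                        attn[modality] = self.last_cls_attention
                else:
                    h = self._encode_mean(x, mask)
            else:
                h = zero
            parts["h_rgb" if modality == APPEARANCE else "h_flow"] = h
        h_agg = parts["h_rgb"] + parts["h_flow"]
        p = self.params
        h_video = (h_agg @ p["proj_W1"] + p["proj_b1"]).relu() @ p["proj_W2"] + p["proj_b2"]
        parts["h_agg"] = h_agg
        parts["h_video"] = h_video
        if capture_attention:
            self._modality_attention = attn
        return h_video, parts

    def project(self, h_agg: np.ndarray | Tensor) -> Tensor:
        """Two-layer projection head with a ReLU between the linear maps."""
        h = h_agg if isinstance(h_agg, Tensor) else Tensor(np.asarray(h_agg, dtype=np.float64))
        if not np.all(np.isfinite(h.data)):
            raise ValueError("non-finite aggregate embedding")
        p = self.params
        return (h @ p["proj_W1"] + p["proj_b1"]).relu() @ p["proj_W2"] + p["proj_b2"]

    def frame_importance(self, sample: VideoSample) -> np.ndarray:
        """Attention weight per valid frame, from the classification token.

        Weights come from the final encoder layer's attention out of the
        classification token, averaged over heads and over the two modality
        streams, renormalised over valid frames.  Padded frames get weight 0.
        """
        if not self.config.use_self_attention:
            raise ValueError("frame importance requires the self-attention encoder")
        streams = [s for s in (sample.appearance, sample.motion)
                   if s is not None and s.modality in self.config.modalities]
        if not streams:
            raise ValueError("sample has no stream for the configured modalities")
        t = streams[0].n_frames
        acc = np.zeros(t)
        for s in streams:
            self.encode_modality(s.vectors[None], s.valid_mask[None], capture_attention=True)
            acc += self.last_cls_attention[0].mean(axis=0)
        mask = streams[0].valid_mask
        if not mask.any():
            raise ValueError("sample has no valid frame")
        w = np.where(mask, acc, 0.0)
        return w / w.sum()


def encode_modality(seq: FrameFeatureSequence, net: SAISNet) -> np.ndarray:
    """Single-sequence wrapper over :meth:`SAISNet.encode_modality`."""
    return net.encode_modality(seq.vectors[None], seq.valid_mask[None]).data[0]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, net: SAISNet) -> None:
    """Serialise parameters + config + category names into one .npz file."""
    meta = {"config": asdict(net.config), "categories": net.categories, "format": 1}
    arrays = {f"param::{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> SAISNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["modalities"] = tuple(cfg_d["modalities"])
        cfg = EncoderConfig(**cfg_d)
        net = SAISNet(cfg, meta["categories"], np.random.default_rng(0))
        net.load_state_dict({k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")})
    return net
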