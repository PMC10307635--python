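"""Scikit-learn style estimator around the two-stream prototype classifier.

:class:`TemporalPrototypeClassifier` follows the sklearn estimator contract
(``fit`` / ``predict`` / ``predict_proba``, ``get_params`` / ``set_params``,
fitted attributes with a trailing underscore) so it composes with pipelines
and model selection.  Samples are :class:`~sais.features.VideoSample` objects
(or bare ``(appearance, motion)`` matrix pairs) rather than a 2-D design
matrix, because clips have variable length and two modalities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import APPEARANCE, MOTION, VideoSample
from .model import EncoderConfig, SAISNet, info_nce_loss

__all__ = ["TemporalPrototypeClassifier"]


def _sample_arrays(x) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Canonicalise one sample to (appearance, motion, valid_mask)."""
    if isinstance(x, VideoSample):
        app = x.appearance.vectors if x.appearance is not None else None
        flow = x.motion.vectors if x.motion is not None else None
        ref = x.appearance if x.appearance is not None else x.motion
        return app, flow, ref.valid_mask.copy()
    app, flow = x
    ref = app if app is not None else flow
    return (
        None if app is None else np.asarray(app, dtype=np.float64),
        None if flow is None else np.asarray(flow, dtype=np.float64),
        np.ones(len(ref), dtype=bool),
    )


def collate_arrays(batch) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-pad a batch of variable-length samples to the batch max length.

    Returns ``(x_app, x_flow, mask)`` with shapes (B, T_max, D) twice and
    (B, T_max); mask is False exactly on the padded rows.
    """
    parts = [_sample_arrays(x) for x in batch]
    t_max = max(len(m) for _, _, m in parts)
    dims = [a.shape[1] for a, f, _ in parts for a in (a, f) if a is not None]
    d = dims[0]
    b = len(parts)
    x_app = np.zeros((b, t_max, d))
    x_flow = np.zeros((b, t_max, d))
    mask = np.zeros((b, t_max), dtype=bool)
    for i, (app, flow, m) in enumerate(parts):
        t = len(m)
        if app is not None:
            x_app[i, :t] = app
        if flow is not None:
            x_flow[i, :t] = flow
        mask[i, :t] = m
    return x_app, x_flow, mask


class TemporalPrototypeClassifier(ClassifierMixin, BaseEstimator):
    """Two-stream temporal transformer trained with prototype InfoNCE.

    Parameters mirror the reference training recipe: SGD with learning rate
    0.1, mini-batches of eight clips, shared encoder across modalities, and
    classification by softmax over cosine similarities to learned category
    prototypes.

    Parameters
    ----------
    embed_dim : int
        Dimension E of video embeddings and prototypes.
    n_layers, n_heads, max_t, ffn_mult, dropout : encoder architecture.
    use_self_attention : bool
        If False, replace the encoder by a mean over valid frames (ablation).
    modalities : tuple of str
        Streams actually used; a missing stream contributes a zero summary.
    batch_size, learning_rate, n_epochs : optimisation settings.
    validation : bool
        If True and validation data are passed to :meth:`fit`, keep the
        parameters from the epoch with the lowest validation loss.
    random_state : int or None
        Seed for parameter initialisation, shuffling and dropout.

    Attributes
    ----------
    classes_ : (C,) array of category labels (sorted).
    net_ : the fitted network (parameters, prototypes, config).
    loss_curve_ : per-epoch mean training loss.
    val_loss_curve_ : per-epoch mean validation loss (when validation data given).
    best_epoch_ : epoch whose parameters were kept.
    """

    def __init__(
        self,
        embed_dim: int = 256,
        n_layers: int = 4,
        n_heads: int = 8,
        max_t: int = 512,
        ffn_mult: int = 4,
        dropout: float = 0.1,
        use_self_attention: bool = True,
        modalities: tuple[str, ...] = (APPEARANCE, MOTION),
        batch_size: int = 8,
        learning_rate: float = 0.1,
        n_epochs: int = 50,
        validation: bool = True,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.embed_dim = embed_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.max_t = max_t
        self.ffn_mult = ffn_mult
        self.dropout = dropout
        self.use_self_attention = use_self_attention
        self.modalities = modalities
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.validation = validation
        self.random_state = random_state
        self.verbose = verbose

    # -- internals ------------------------------------------------------------
    def _forward(self, batch, training=False, rng=None):
        x_app, x_flow, mask = collate_arrays(batch)
        if APPEARANCE not in self.modalities:
            x_app = None
        if MOTION not in self.modalities:
            x_flow = None
        h_video, _ = self.net_.forward(x_app, x_flow, mask, training=training, rng=rng)
        return h_video

    def _mean_loss(self, X, y_idx) -> float:
        total, n = 0.0, 0
        for start in range(0, len(X), 64):
            chunk = X[start:start + 64]
            labels = y_idx[start:start + 64]
            h = self._forward(chunk)
            total += float(info_nce_loss(h, labels, self.net_.params["prototypes"]).data)
            n += len(chunk)
        return total / n

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on a list of clips; optionally select the best epoch on a held-out set."""
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two categories to fit prototypes")
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_to_idx[v] for v in y])

        app0, flow0, _ = _sample_arrays(X[0])
        dim = (app0 if app0 is not None else flow0).shape[1]
        self.n_features_in_ = dim
        cfg = EncoderConfig(
            dim=dim,
            embed_dim=self.embed_dim,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            max_t=self.max_t,
            ffn_mult=self.ffn_mult,
            dropout=self.dropout,
            use_self_attention=self.use_self_attention,
            modalities=tuple(self.modalities),
        )
        rng = np.random.default_rng(self.random_state)
        self.net_ = SAISNet(cfg, [str(c) for c in self.classes_], rng)

        use_val = self.validation and X_val is not None and len(X_val) > 0
        if use_val:
            yv_idx = np.array([class_to_idx[v] for v in np.asarray(y_val)])
        self.loss_curve_: list[float] = []
        self.val_loss_curve_: list[float] = []
        best = (np.inf, None, -1)
        n = len(X)
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                take = order[start:start + self.batch_size]
                batch = [X[i] for i in take]
                labels = y_idx[take]
                h = self._forward(batch, training=True, rng=rng)
                loss = info_nce_loss(h, labels, self.net_.params["prototypes"])
                self.net_.zero_grad()
                loss.backward()
                self.net_.sgd_step(self.learning_rate)
                total += float(loss.data)
            self.loss_curve_.append(total / n)
            if use_val:
                vl = self._mean_loss(X_val, yv_idx)
                self.val_loss_curve_.append(vl)
                if vl < best[0]:
                    best = (vl, self.net_.state_dict(), epoch)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.n_epochs} "
                      f"train {self.loss_curve_[-1]:.4f}"
                      + (f" val {self.val_loss_curve_[-1]:.4f}" if use_val else ""))
        if use_val and best[1] is not None:
            self.net_.load_state_dict(best[1])
            self.best_epoch_ = best[2]
        else:
            self.best_epoch_ = self.n_epochs - 1
        return self

    def decision_function(self, X) -> np.ndarray:
        """Cosine similarity of each clip's video embedding to each prototype."""
        self._check_fitted()
        from .model import cosine_scores

        out = []
        for start in range(0, len(X), 64):
            h = self._forward(X[start:start + 64])
            out.append(cosine_scores(h.data, self.net_.params["prototypes"].data).data)
        return np.vstack(out)

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        # np.argmax takes the first maximum: ties break to the lowest index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def frame_importance(self, sample: VideoSample) -> np.ndarray:
        """Per-frame attention weights explaining one clip's classification."""
        self._check_fitted()
        return self.net_.frame_importance(sample)

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")

    # -- persistence ----------------------------------------------------------
    def to_checkpoint(self, path) -> None:
        """Serialise the fitted network (parameters, prototypes, config)."""
        self._check_fitted()
        from .model import save_checkpoint

        save_checkpoint(path, self.net_)

    @classmethod
    def from_checkpoint(cls, path) -> "TemporalPrototypeClassifier":
        """Rebuild a fitted estimator from a checkpoint file."""
        from .model import load_checkpoint

        net = load_checkpoint(path)
        cfg = net.config
        clf = cls(
            embed_dim=cfg.embed_dim, n_layers=cfg.n_layers, n_heads=cfg.n_heads,
            max_t=cfg.max_t, ffn_mult=cfg.ffn_mult, dropout=cfg.dropout,
            use_self_attention=cfg.use_self_attention, modalities=cfg.modalities,
        )
        clf.net_ = net
        clf.classes_ = np.array(net.categories)
        clf.n_features_in_ = cfg.dim
        return clf
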