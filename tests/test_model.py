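"""Forward-pass semantics: masking, aggregation, cosine classification, InfoNCE."""

import numpy as np
import pytest

from sais.features import APPEARANCE, MOTION, FrameFeatureSequence, VideoSample
from sais.model import (
    EncoderConfig,
    PrototypeBank,
    SAISNet,
    aggregate,
    classify,
    cosine_scores,
    info_nce_loss,
)


def _batch(rng, b=2, t=5, d=8):
    x = rng.normal(size=(b, t, d))
    mask = np.ones((b, t), dtype=bool)
    return x, mask


class TestEncoder:
    def test_masking_invariance_padding_never_changes_output(self, tiny_net):
        rng = np.random.default_rng(3)
        x, mask = _batch(rng)
        base = tiny_net.encode_modality(x, mask).data
        xp = np.concatenate([x, np.zeros((2, 3, 8))], axis=1)
        mp = np.concatenate([mask, np.zeros((2, 3), dtype=bool)], axis=1)
        padded = tiny_net.encode_modality(xp, mp).data
        assert np.max(np.abs(base - padded)) <= 1e-6

    def test_capacity_error_beyond_max_t(self, tiny_net):
        x = np.zeros((1, 40, 8))
        with pytest.raises(ValueError, match="capacity"):
            tiny_net.encode_modality(x, np.ones((1, 40), dtype=bool))

    def test_mean_ablation_is_permutation_invariant(self):
        cfg = EncoderConfig(dim=8, embed_dim=6, n_layers=1, n_heads=2, max_t=16,
                            dropout=0.0, use_self_attention=False)
        net = SAISNet(cfg, ["a", "b"], np.random.default_rng(0))
        rng = np.random.default_rng(4)
        x, mask = _batch(rng, b=1)
        perm = rng.permutation(5)
        out = net.encode_modality(x, mask).data
        out_p = net.encode_modality(x[:, perm], mask).data
        assert np.allclose(out, out_p)
        assert np.allclose(out[0], x[0].mean(axis=0))

    def test_positional_embeddings_break_permutation_symmetry(self, tiny_net):
        rng = np.random.default_rng(5)
        x, mask = _batch(rng, b=1, t=6)
        perm = np.array([3, 0, 5, 1, 4, 2])
        with_pos = tiny_net.encode_modality(x, mask).data
        with_pos_p = tiny_net.encode_modality(x[:, perm], mask).data
        assert not np.allclose(with_pos, with_pos_p, atol=1e-6)
        # zeroing the positional table restores symmetry of the cls summary
        saved = tiny_net.params["pos"].data.copy()
        tiny_net.params["pos"].data[:] = 0.0
        try:
            no_pos = tiny_net.encode_modality(x, mask).data
            no_pos_p = tiny_net.encode_modality(x[:, perm], mask).data
        finally:
            tiny_net.params["pos"].data = saved
        assert np.allclose(no_pos, no_pos_p, atol=1e-9)

    def test_single_layer_head_matches_dense_attention_oracle(self):
        """Hand-rolled dense attention + FFN reproduces the encoder exactly."""
        cfg = EncoderConfig(dim=4, embed_dim=3, n_layers=1, n_heads=1, max_t=8,
                            dropout=0.0)
        net = SAISNet(cfg, ["a", "b"], np.random.default_rng(7))
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1, 2, 4))
        out = net.encode_modality(x, np.ones((1, 2), dtype=bool)).data[0]

        p = {k: v.data for k, v in net.params.items()}
        h = np.vstack([p["e_cls"], x[0] + p["pos"][:2]])  # (3, 4)
        q, k, v = h @ p["l0.Wq"], h @ p["l0.Wk"], h @ p["l0.Wv"]
        scores = q @ k.T / np.sqrt(4)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        h1 = h + (w @ v) @ p["l0.Wo"]

        def ln(z, g, b):
            mu, var = z.mean(-1, keepdims=True), z.var(-1, keepdims=True)
            return (z - mu) / np.sqrt(var + 1e-5) * g + b

        h1 = ln(h1, p["l0.ln1_g"], p["l0.ln1_b"])
        ffn = np.maximum(h1 @ p["l0.W1"], 0) @ p["l0.W2"]
        expected = ln(h1 + ffn, p["l0.ln2_g"], p["l0.ln2_b"])[0]
        assert np.max(np.abs(out - expected)) < 1e-9


class TestAggregateProject:
    def test_sum_identity_and_commutativity(self):
        x = np.array([1.0, 2.0])
        assert np.array_equal(aggregate(x, np.zeros(2)), x)
        assert np.array_equal(aggregate(np.array([1.0, 2.0]), np.array([3.0, 4.0])),
                              np.array([4.0, 6.0]))
        a, b = np.random.default_rng(0).normal(size=(2, 5))
        assert np.array_equal(aggregate(a, b), aggregate(b, a))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate(np.zeros(3), np.zeros(4))

    def test_projection_output_dim_and_nonfinite_guard(self, tiny_net):
        out = tiny_net.project(np.zeros((2, 8)))
        assert out.data.shape == (2, 6)
        with pytest.raises(ValueError):
            tiny_net.project(np.full((1, 8), np.nan))

    def test_default_config_projects_to_256(self):
        assert EncoderConfig().embed_dim == 256

    def test_identity_head_reproduces_rectified_input(self, tiny_net):
        saved = {k: tiny_net.params[k].data.copy()
                 for k in ("proj_W1", "proj_b1", "proj_W2", "proj_b2")}
        try:
            tiny_net.params["proj_W1"].data = np.eye(8)[:, :6]
            tiny_net.params["proj_b1"].data[:] = 0
            tiny_net.params["proj_W2"].data = np.eye(6)
            tiny_net.params["proj_b2"].data[:] = 0
            x = np.array([[1.0, -2.0, 3.0, -4.0, 5.0, -6.0, 7.0, 8.0]])
            assert np.allclose(tiny_net.project(x).data[0],
                               np.maximum(x[0, :6], 0))
        finally:
            for k, v in saved.items():
                tiny_net.params[k].data = v


class TestClassify:
    def test_orthogonal_prototype_softmax(self):
        bank = PrototypeBank(np.array([[1.0, 0.0], [0.0, 1.0]]), ["a", "b"])
        probs = classify(np.array([1.0, 0.0]), bank)
        expected = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        assert np.allclose(probs, expected, atol=1e-9)
        assert abs(probs[0] - 0.7311) < 1e-4

    def test_identical_prototypes_give_uniform_mass(self):
        bank = PrototypeBank(np.ones((3, 4)), ["a", "b", "c"])
        probs = classify(np.array([1.0, 2.0, 3.0, 4.0]), bank)
        assert np.allclose(probs, 1 / 3)

    def test_scale_invariance_of_cosine(self):
        rng = np.random.default_rng(9)
        bank = PrototypeBank(rng.normal(size=(4, 6)), list("abcd"))
        h = rng.normal(size=6)
        assert np.allclose(classify(h, bank), classify(10 * h, bank))

    def test_zero_embedding_rejected(self):
        bank = PrototypeBank(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError):
            classify(np.zeros(2), bank)

    def test_probabilities_valid_for_random_inputs(self):
        rng = np.random.default_rng(10)
        bank = PrototypeBank(rng.normal(size=(5, 7)), list("abcde"))
        for _ in range(20):
            p = classify(rng.normal(size=7), bank)
            assert np.all(p >= 0) and abs(p.sum() - 1) < 1e-9


def brute_force_info_nce(h, labels, protos):
    """Independent evaluation of the prototype InfoNCE sum."""
    total = 0.0
    for hi, c in zip(h, labels):
        sims = [float(np.dot(hi, p) / (np.linalg.norm(hi) * np.linalg.norm(p)))
                for p in protos]
        total += -np.log(np.exp(sims[c]) / np.sum(np.exp(sims)))
    return total


class TestInfoNCE:
    def test_closed_form_single_sample(self):
        # cosine +1 to own prototype, -1 to the other
        h = np.array([[2.0, 0.0]])
        protos = np.array([[1.0, 0.0], [-1.0, 0.0]])
        loss = float(info_nce_loss(h, [0], protos).data)
        assert abs(loss - (-np.log(np.e / (np.e + np.exp(-1.0))))) < 1e-12
        assert abs(loss - 0.1269) < 1e-4

    def test_equal_similarities_give_b_log_c(self):
        protos = np.tile(np.array([1.0, 1.0]), (4, 1))
        h = np.ones((3, 2))
        loss = float(info_nce_loss(h, [0, 1, 2], protos).data)
        assert abs(loss - 3 * np.log(4)) < 1e-9

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            b, c, e = rng.integers(1, 6), rng.integers(2, 5), rng.integers(2, 8)
            h = rng.normal(size=(b, e))
            protos = rng.normal(size=(c, e))
            labels = rng.integers(0, c, size=b)
            got = float(info_nce_loss(h, labels, protos).data)
            want = brute_force_info_nce(h, labels, protos)
            assert abs(got - want) <= 1e-9 * max(1.0, abs(want))

    def test_label_without_prototype_rejected(self):
        with pytest.raises(ValueError):
            info_nce_loss(np.ones((1, 3)), [5], np.eye(3))

    def test_nonnegative(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            h = rng.normal(size=(4, 5))
            protos = rng.normal(size=(3, 5))
            assert float(info_nce_loss(h, rng.integers(0, 3, 4), protos).data) >= 0

    def test_prototype_gradient_matches_finite_differences(self):
        from sais._autodiff import Tensor

        rng = np.random.default_rng(13)
        h = rng.normal(size=(3, 4))
        protos = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        labels = np.array([0, 2, 1])
        loss = info_nce_loss(h, labels, protos)
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (2, 3)]:
            orig = protos.data[idx]
            protos.data[idx] = orig + eps
            lp = float(info_nce_loss(h, labels, Tensor(protos.data)).data)
            protos.data[idx] = orig - eps
            lm = float(info_nce_loss(h, labels, Tensor(protos.data)).data)
            protos.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(protos.grad[idx] - fd) <= 1e-4 * max(1.0, abs(fd))


class TestFrameImportance:
    def _sample(self, rng, t=6, d=32):
        idx = np.arange(t)
        return VideoSample(
            "v", 0.0, 1.0, "hook",
            FrameFeatureSequence(APPEARANCE, rng.normal(size=(t, d)), idx, 30.0),
            FrameFeatureSequence(MOTION, rng.normal(size=(t, d)), idx, 30.0),
        )

    def test_weights_sum_to_one_over_valid_frames(self, small_trained_clf):
        rng = np.random.default_rng(14)
        w = small_trained_clf.frame_importance(self._sample(rng))
        assert np.all(w >= 0) and abs(w.sum() - 1.0) < 1e-9

    def test_padded_frames_get_zero_weight(self, small_trained_clf):
        rng = np.random.default_rng(15)
        s = self._sample(rng)
        padded = VideoSample(s.video_id, s.start_s, s.end_s, s.category,
                             s.appearance.pad_to(9), s.motion.pad_to(9))
        w = small_trained_clf.frame_importance(padded)
        assert np.all(w[6:] == 0) and abs(w.sum() - 1.0) < 1e-9

    def test_single_frame_clip_gets_full_weight(self, small_trained_clf):
        rng = np.random.default_rng(16)
        w = small_trained_clf.frame_importance(self._sample(rng, t=1))
        assert np.allclose(w, [1.0])

    def test_mean_ablation_cannot_explain(self):
        cfg = EncoderConfig(dim=8, embed_dim=4, n_layers=1, n_heads=2, max_t=8,
                            use_self_attention=False)
        net = SAISNet(cfg, ["a", "b"], np.random.default_rng(0))
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError, match="self-attention"):
            net.frame_importance(self._sample(rng, d=8))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, small_trained_clf, gesture_study, tmp_path):
        from sais.estimators import TemporalPrototypeClassifier

        clips = gesture_study["clips"][:8]
        path = tmp_path / "ckpt.npz"
        small_trained_clf.to_checkpoint(path)
        restored = TemporalPrototypeClassifier.from_checkpoint(path)
        assert np.array_equal(restored.classes_, small_trained_clf.classes_)
        assert np.allclose(restored.predict_proba(clips),
                           small_trained_clf.predict_proba(clips))
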