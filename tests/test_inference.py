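"""Window curation, TTA, bagging, entropy abstention and event chaining."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sais.inference import (
    EnsembleCell,
    EventInterval,
    InferenceConfig,
    VideoEventDecoder,
    Window,
    activity_profile,
    assign_timespans,
    bag,
    chain_events,
    curate_windows,
    entropy,
    entropy_abstain,
    tta_inputs,
)


class TestCurateWindows:
    def test_subphase_worked_example_20s(self):
        windows = curate_windows(20.0, "subphase")
        a1 = [(w.start_s, w.end_s) for w in windows if w.approach == 1]
        a2 = [(w.start_s, w.end_s) for w in windows if w.approach == 2]
        assert a1 == [(0, 10), (5, 15), (10, 20)]
        assert a2 == [(0, 5), (5, 10), (10, 15), (15, 20)]

    def test_gesture_one_second_tiling(self):
        windows = curate_windows(3.0, "gesture")
        assert [(w.start_s, w.end_s) for w in windows] == [(0, 1), (1, 2), (2, 3)]

    def test_too_short_video_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning):
            assert curate_windows(0.5, "gesture") == []

    def test_interior_timespan_covered_by_three_windows(self):
        windows = curate_windows(40.0, "subphase")
        span = (10.0, 20.0)
        contributors = [w for w in windows
                        if span in assign_timespans(w, "subphase", 40.0)]
        approaches = sorted(w.approach for w in contributors)
        assert approaches == [1, 2, 2]


class TestTTA:
    def test_subphase_stride_with_standard_offsets(self):
        variants = tta_inputs(90, "subphase", offsets=(0, 3, 6))
        assert variants[0].tolist() == [0, 10, 20, 30, 40, 50, 60, 70, 80]
        assert variants[1].tolist() == [3, 13, 23, 33, 43, 53, 63, 73, 83]
        assert variants[2].tolist() == [6, 16, 26, 36, 46, 56, 66, 76, 86]

    def test_zero_offset_equals_plain_sampling(self):
        (only,) = tta_inputs(90, "gesture", offsets=(0,))
        assert only.tolist() == [0, 9, 18, 27, 36, 45, 54, 63, 72, 81]

    def test_variants_share_no_frame_index(self):
        variants = tta_inputs(90, "subphase", offsets=(0, 3, 6))
        sets = [set(v.tolist()) for v in variants]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])

    def test_overflowing_indices_dropped(self):
        variants = tta_inputs(30, "gesture", offsets=(0, 6))
        assert variants[1].max() < 30
        assert len(variants[1]) < len(variants[0])


class TestBagging:
    def test_mean_of_two_opposed_cells(self):
        span = (0.0, 10.0)
        cells = [EnsembleCell(span, [1.0, 0.0], 1, 1, 0),
                 EnsembleCell(span, [0.0, 1.0], 2, 1, 0)]
        assert np.allclose(bag(cells), [0.5, 0.5])

    def test_identical_cells_idempotent(self):
        span = (0.0, 10.0)
        cells = [EnsembleCell(span, [0.3, 0.7], 1, f, t) for f in (1, 2) for t in (0, 1)]
        assert np.allclose(bag(cells), [0.3, 0.7])

    def test_mixed_timespans_rejected(self):
        with pytest.raises(ValueError):
            bag([EnsembleCell((0.0, 10.0), [1.0, 0.0], 1, 1, 0),
                 EnsembleCell((5.0, 15.0), [1.0, 0.0], 1, 1, 0)])

    def test_result_is_probability_mass(self):
        rng = np.random.default_rng(0)
        span = (0.0, 5.0)
        cells = []
        for i in range(9):
            p = rng.dirichlet(np.ones(4))
            cells.append(EnsembleCell(span, p, 1, i, 0))
        assert abs(bag(cells).sum() - 1.0) < 1e-9


class TestEntropyAbstention:
    def test_uniform_six_categories_abstains_at_1_74(self):
        uniform = np.full(6, 1 / 6)
        assert abs(entropy(uniform) - np.log(6)) < 1e-12
        assert entropy_abstain(uniform, 1.74) is None

    def test_one_hot_is_kept(self):
        one_hot = np.array([0.0, 1.0, 0.0])
        assert entropy(one_hot) == 0.0
        assert entropy_abstain(one_hot, 1.74) == 1

    def test_default_gesture_threshold_for_six_categories(self):
        assert InferenceConfig(regime="gesture").resolved_s_thresh(6) == 1.74

    def test_threshold_above_ln_c_rejected(self):
        with pytest.raises(ValueError, match="ln C"):
            InferenceConfig(regime="gesture", s_thresh=1.74).resolved_s_thresh(3)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
           st.floats(0.05, 1.5), st.floats(0.0, 0.4))
    def test_abstention_monotone_in_threshold(self, raw, thresh, bump):
        p = np.asarray(raw) / np.sum(raw)
        low = entropy_abstain(p, thresh)
        high = entropy_abstain(p, thresh + bump)
        if low is not None:  # raising the threshold never removes a kept label
            assert high == low


class TestChaining:
    def test_retraction_worked_example(self):
        preds = [((10.0, 11.0), "retraction"), ((11.0, 12.0), "retraction"),
                 ((15.0, 16.0), "retraction")]
        events = chain_events(preds, chain_gap=2.0)
        assert events == [EventInterval("retraction", 10.0, 12.0),
                          EventInterval("retraction", 15.0, 16.0)]
        assert events[0].duration == 2.0 and events[1].duration == 1.0

    def test_different_categories_never_merge(self):
        preds = [((0.0, 1.0), "hook"), ((1.0, 2.0), "clip")]
        events = chain_events(preds, chain_gap=5.0)
        assert len(events) == 2

    def test_overlapping_predictions_unioned(self):
        preds = [((0.0, 10.0), "x"), ((5.0, 15.0), "x")]
        assert chain_events(preds, 3.0) == [EventInterval("x", 0.0, 15.0)]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        preds = []
        t = 0.0
        for _ in range(30):
            t += rng.uniform(0.5, 4.0)
            preds.append(((t, t + 1.0), rng.choice(["a", "b"])))
        once = chain_events(preds, 2.0)
        twice = chain_events([((e.start_s, e.end_s), e.category) for e in once], 2.0)
        assert once == twice

    def test_chained_events_disjoint_per_category(self):
        rng = np.random.default_rng(2)
        preds = [((s, s + 1.0), "a") for s in np.sort(rng.uniform(0, 50, 40))]
        events = chain_events(preds, 2.0)
        for e1, e2 in zip(events, events[1:]):
            assert e2.start_s >= e1.end_s
        assert sum(e.duration for e in events) <= 51.0


class TestActivityProfile:
    def test_low_skill_ratio(self):
        events = [EventInterval("needle_handling", i, i + 1) for i in range(4)]
        out = activity_profile(events, low_skill=[1.0, 0.0, 0.0, 0.0])
        assert out["low_skill_ratio"] == 0.25
        assert len(out["timeline"]) == 4

    def test_no_events_ratio_undefined(self):
        assert activity_profile([], low_skill=[])["low_skill_ratio"] is None

    def test_all_low_skill(self):
        events = [EventInterval("x", 0, 1), EventInterval("x", 2, 3)]
        assert activity_profile(events, [0.9, 0.8])["low_skill_ratio"] == 1.0


class TestDecoder:
    def test_ensemble_accounting_90_cells_per_interior_timespan(self, small_trained_clf):
        """2 window approaches x 10 folds x 3 TTAs = 90 outputs per 10-s timespan."""
        decoder = VideoEventDecoder([small_trained_clf] * 10,
                                    InferenceConfig(regime="subphase"))
        rng = np.random.default_rng(3)
        app = rng.normal(size=(900, 32))  # 30 s at 30 fps
        cells = decoder.collect_cells(app, app.copy(), fps=30.0)
        interior = {span: v for span, v in cells.items()
                    if span[0] >= 5 and span[1] <= 25}
        assert interior, "expected interior timespans"
        for span, cell_list in interior.items():
            assert len(cell_list) == 90, span
            by_prov = {(c.approach, c.fold, c.tta) for c in cell_list}
            assert len(by_prov) == 90  # distinct provenance triples

    def test_decode_is_deterministic(self, gesture_ensemble, gesture_study):
        models, _ = gesture_ensemble
        cfg = InferenceConfig(regime="gesture", background_category="background")
        decoder = VideoEventDecoder(models, cfg)
        app = gesture_study["appearance"][:3000]
        flow = gesture_study["flow"][:3000]
        r1 = decoder.decode(app, flow, 30.0)
        r2 = decoder.decode(app, flow, 30.0)
        assert r1.events == r2.events
        assert np.allclose(r1.bagged.drop(columns="kept").to_numpy(dtype=float),
                           r2.bagged.drop(columns="kept").to_numpy(dtype=float))

    def test_evented_duration_bounded_by_video_duration(self, gesture_ensemble, gesture_study):
        models, _ = gesture_ensemble
        decoder = VideoEventDecoder(
            models, InferenceConfig(regime="gesture", background_category="background"))
        app = gesture_study["appearance"][:3000]
        res = decoder.decode(app, gesture_study["flow"][:3000], 30.0)
        duration = 3000 / 30.0
        by_cat = {}
        for e in res.events:
            by_cat.setdefault(e.category, 0.0)
            by_cat[e.category] += e.duration
        assert all(v <= duration for v in by_cat.values())

    def test_mismatched_category_sets_rejected(self, small_trained_clf):
        other = type(small_trained_clf)()
        other.classes_ = np.array(["x", "y"])
        other.net_ = small_trained_clf.net_
        with pytest.raises(ValueError):
            VideoEventDecoder([small_trained_clf, other], InferenceConfig())
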