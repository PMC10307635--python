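"""Decoding entire untrimmed videos without annotations.

The trained clip classifier is slid over a whole video: candidate windows are
curated per regime (for suturing subphases, 10-s windows with 5-s overlap plus
5-s non-overlapping windows; for dissection gestures, 1-s non-overlapping
windows), every window is classified under three test-time augmentations
(start-frame offsets 0, 3 and 6), all probabilistic outputs landing on the
same timespan across window approaches, cross-validation folds and
augmentations are averaged (bagging), high-entropy averages are abstained
from, and the surviving per-timespan labels are chained over time into
discrete activity events.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import extract_clip, sample_frame_indices, task_for_regime

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "EnsembleCell",
    "EventInterval",
    "curate_windows",
    "tta_inputs",
    "assign_timespans",
    "bag",
    "entropy",
    "entropy_abstain",
    "chain_events",
    "activity_profile",
    "VideoEventDecoder",
]

SUBPHASE = "subphase"
GESTURE = "gesture"

#: default chaining gaps in seconds per regime
DEFAULT_CHAIN_GAP = {SUBPHASE: 3.0, GESTURE: 2.0}
#: entropy threshold used for the six-category gesture vocabulary
GESTURE_S_THRESH = 1.74


@dataclass(frozen=True)
class InferenceConfig:
    """Settings of the full-video decoding stack.

    ``s_thresh=None`` resolves at decode time: 1.74 for the gesture regime
    (tuned for a six-category vocabulary) and ``0.95 * ln C`` otherwise.
    ``chain_gap=None`` resolves to 3 s for subphases and 2 s for gestures.
    When the ensemble was trained with an explicit idle/background category,
    name it in ``background_category``: timespans classified as background
    are dropped (not reported as activity events) before chaining.
    """

    regime: str = SUBPHASE
    tta_offsets: tuple[int, ...] = (0, 3, 6)
    s_thresh: float | None = None
    chain_gap: float | None = None
    n_folds: int = 10
    background_category: str | None = None

    def __post_init__(self):
        if self.regime not in (SUBPHASE, GESTURE):
            raise ValueError(f"unknown regime {self.regime!r}")
        if len(set(self.tta_offsets)) != len(self.tta_offsets) or min(self.tta_offsets) < 0:
            raise ValueError("tta offsets must be distinct and >= 0")
        if self.chain_gap is not None and self.chain_gap < 0:
            raise ValueError("chain_gap must be >= 0")
        if self.s_thresh is not None and self.s_thresh <= 0:
            raise ValueError("s_thresh must be positive")

    def resolved_s_thresh(self, n_categories: int) -> float:
        if self.s_thresh is not None:
            if self.s_thresh > np.log(n_categories) + 1e-12:
                raise ValueError(
                    f"s_thresh {self.s_thresh} exceeds ln C = {np.log(n_categories):.4f}; "
                    "no mass over that many categories can reach it"
                )
            return self.s_thresh
        if self.regime == GESTURE and n_categories == 6:
            return GESTURE_S_THRESH
        return 0.95 * np.log(n_categories)

    def resolved_chain_gap(self) -> float:
        return DEFAULT_CHAIN_GAP[self.regime] if self.chain_gap is None else self.chain_gap


@dataclass(frozen=True)
class Window:
    start_s: float
    end_s: float
    approach: int


@dataclass(frozen=True)
class EnsembleCell:
    """One probabilistic output with its provenance.

    ``approach`` indexes the window output within the timespan (P = 1 for the
    sliding 10-s window, P = 2 and 3 for the two tiled 5-s windows; gesture
    windows always carry P = 1), ``fold`` the cross-validation model and
    ``tta`` the test-time augmentation variant.
    """

    timespan: tuple[float, float]
    probs: np.ndarray
    approach: int
    fold: int
    tta: int

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("probs must be a probability mass")


@dataclass(frozen=True)
class EventInterval:
    """A decoded activity occurrence."""

    category: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def curate_windows(duration_s: float, regime: str) -> list[Window]:
    """Candidate windows over a whole video, per regime.

    Subphase regime: approach 1 slides 10-s windows by 5 s (to catch boundary
    activity); approach 2 tiles non-overlapping 5-s windows.  Gesture regime:
    non-overlapping 1-s windows.  Trailing partial windows are dropped.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    windows: list[Window] = []
    if regime == SUBPHASE:
        specs = [(10.0, 5.0, 1), (5.0, 5.0, 2)]
    elif regime == GESTURE:
        specs = [(1.0, 1.0, 2)]
    else:
        raise ValueError(f"unknown regime {regime!r}")
    for length, step, approach in specs:
        start = 0.0
        while start + length <= duration_s + 1e-9:
            windows.append(Window(start, start + length, approach))
            start += step
    if not windows:
        warnings.warn(
            f"video of {duration_s}s is shorter than the smallest {regime} window",
            stacklevel=2,
        )
    return windows


def tta_inputs(n_frames: int, regime: str, offsets=(0, 3, 6)) -> list[np.ndarray]:
    """Frame-index sets for test-time augmentation of one window.

    Each variant keeps the regime's sampling stride but shifts the start
    frame by an offset; shifted indices that fall beyond the window are
    dropped.  With strides of ~10 frames and offsets 0/3/6 the variants share
    no frame index.
    """
    base = sample_frame_indices(task_for_regime(regime), n_frames)
    out = []
    for k in offsets:
        shifted = base + k
        out.append(shifted[shifted < n_frames])
    return out


def assign_timespans(window: Window, regime: str, duration_s: float) -> list[tuple[float, float]]:
    """Timespans on which a window's probabilistic output is accumulated.

    For subphases, outputs are pooled on 10-s timespans laid on the 5-s grid:
    an approach-1 window votes on the timespan sharing its start; a 5-s
    approach-2 window votes on both 10-s timespans containing it.  Gesture
    windows vote on themselves.
    """
    if regime == GESTURE:
        return [(window.start_s, window.end_s)]
    spans = []
    if window.approach == 1:
        spans = [(window.start_s, window.start_s + 10.0)]
    else:
        spans = [(window.start_s - 5.0, window.start_s + 5.0),
                 (window.start_s, window.start_s + 10.0)]
    return [(a, b) for a, b in spans if a >= -1e-9 and b <= duration_s + 1e-9]


def bag(cells: list[EnsembleCell]) -> np.ndarray:
    """Average the probabilistic outputs accumulated on one timespan."""
    if not cells:
        raise ValueError("cannot bag an empty cell list")
    spans = {c.timespan for c in cells}
    if len(spans) != 1:
        raise ValueError(f"cells span multiple timespans: {sorted(spans)}")
    return np.mean([c.probs for c in cells], axis=0)


def entropy(probs: np.ndarray) -> float:
    """Shannon entropy in nats, with the 0·log 0 = 0 convention."""
    p = np.asarray(probs, dtype=np.float64)
    terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(-terms.sum())


def entropy_abstain(probs: np.ndarray, s_thresh: float) -> int | None:
    """Return the argmax label index, or None when entropy exceeds the threshold."""
    if entropy(probs) > s_thresh:
        return None
    return int(np.argmax(probs))


def chain_events(
    predictions: list[tuple[tuple[float, float], str]],
    chain_gap: float,
) -> list[EventInterval]:
    """Merge nearby same-category predictions into single events.

    Same-category predictions are first unioned where they overlap, then
    merged whenever the gap to the next one is strictly less than
    ``chain_gap`` seconds.  Different categories never merge.  Idempotent:
    chaining the resulting events again changes nothing.
    """
    if chain_gap < 0:
        raise ValueError("chain_gap must be >= 0")
    by_cat: dict[str, list[tuple[float, float]]] = {}
    for (start, end), cat in predictions:
        by_cat.setdefault(cat, []).append((float(start), float(end)))
    events = []
    for cat, spans in by_cat.items():
        spans.sort()
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start - cur_end < chain_gap:  # negative gap = overlap: union
                cur_end = max(cur_end, end)
            else:
                events.append(EventInterval(cat, cur_start, cur_end))
                cur_start, cur_end = start, end
        events.append(EventInterval(cat, cur_start, cur_end))
    return sorted(events, key=lambda e: (e.start_s, e.end_s, e.category))


def activity_profile(
    events: list[EventInterval],
    low_skill: list[float] | None = None,
) -> dict:
    """Per-case activity timeline plus the ratio of low-skill events.

    ``low_skill`` holds one probability (or 0/1 flag) per event; an event
    counts as low skill when its value exceeds 0.5.  With no events the ratio
    is undefined and reported as None.
    """
    timeline = pd.DataFrame(
        [{"category": e.category, "start_s": e.start_s, "end_s": e.end_s} for e in events]
    )
    ratio = None
    if low_skill is not None:
        if len(low_skill) != len(events):
            raise ValueError("one skill value per event required")
        if events:
            ratio = float(np.mean(np.asarray(low_skill, dtype=np.float64) > 0.5))
    return {"timeline": timeline, "low_skill_ratio": ratio}


@dataclass
class DecodeResult:
    """Everything the full-video decoder produces for one video."""

    events: list[EventInterval]
    kept: list[tuple[tuple[float, float], str]]
    bagged: pd.DataFrame              # per-timespan averaged masses + entropy
    n_cells: dict[tuple[float, float], int]
    categories: list[str]

    def events_frame(self, video_id: str = "video") -> pd.DataFrame:
        return pd.DataFrame(
            [{"video_id": video_id, "category": e.category,
              "start_s": e.start_s, "end_s": e.end_s} for e in self.events]
        )


class VideoEventDecoder:
    """Ensemble decoder turning whole-video feature streams into events.

    Parameters
    ----------
    models : list of fitted TemporalPrototypeClassifier
        One per Monte Carlo fold; all must share the same category set.
    config : InferenceConfig
    """

    def __init__(self, models, config: InferenceConfig = InferenceConfig()):
        if not models:
            raise ValueError("need at least one model")
        cats = [tuple(m.classes_) for m in models]
        if len(set(cats)) != 1:
            raise ValueError("ensemble models disagree on categories")
        self.models = list(models)
        self.config = config
        self.categories = [str(c) for c in models[0].classes_]

    def collect_cells(
        self,
        appearance: np.ndarray,
        motion: np.ndarray,
        fps: float,
        video_id: str = "video",
    ) -> dict[tuple[float, float], list[EnsembleCell]]:
        """Run every (window, TTA, fold) forward pass and pool cells by timespan."""
        cfg = self.config
        duration = appearance.shape[0] / fps
        task = task_for_regime(cfg.regime)
        windows = curate_windows(duration, cfg.regime)
        jobs = []  # (window, tta_index, sample)
        for w in windows:
            for ti, k in enumerate(cfg.tta_offsets):
                try:
                    sample = extract_clip(
                        appearance, motion, fps, video_id,
                        w.start_s, w.end_s, task, offset=int(k),
                    )
                except ValueError:
                    continue
                if sample.appearance.n_frames == 0:
                    continue
                jobs.append((w, ti, sample))
        cells: dict[tuple[float, float], list[EnsembleCell]] = {}
        samples = [j[2] for j in jobs]
        for fold, model in enumerate(self.models, start=1):
            probs = model.predict_proba(samples) if samples else np.empty((0, 0))
            for (w, ti, _), p in zip(jobs, probs):
                for span in assign_timespans(w, cfg.regime, duration):
                    if w.approach == 1 or cfg.regime == GESTURE:
                        p_index = 1
                    else:  # tiled 5-s windows: P=2 for the leading half, 3 trailing
                        p_index = 2 if abs(w.start_s - span[0]) < 1e-9 else 3
                    cells.setdefault(span, []).append(
                        EnsembleCell(span, p, p_index, fold, ti)
                    )
        return cells

    def decode(
        self,
        appearance: np.ndarray,
        motion: np.ndarray,
        fps: float,
        video_id: str = "video",
    ) -> DecodeResult:
        """Windows → TTA → bagging → entropy abstention → event chaining."""
        cfg = self.config
        cells = self.collect_cells(appearance, motion, fps, video_id)
        s_thresh = cfg.resolved_s_thresh(len(self.categories))
        kept, rows = [], []
        for span in sorted(cells):
            s_bar = bag(cells[span])
            s_ent = entropy(s_bar)
            label = entropy_abstain(s_bar, s_thresh)
            rows.append({"start_s": span[0], "end_s": span[1], "entropy": s_ent,
                         "kept": label is not None,
                         **{c: s_bar[i] for i, c in enumerate(self.categories)}})
            if label is not None:
                kept.append((span, self.categories[label]))
        if cfg.background_category is not None:
            kept = [(span, cat) for span, cat in kept if cat != cfg.background_category]
        events = chain_events(kept, cfg.resolved_chain_gap())
        return DecodeResult(
            events=events,
            kept=kept,
            bagged=pd.DataFrame(rows),
            n_cells={span: len(v) for span, v in cells.items()},
            categories=self.categories,
        )
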