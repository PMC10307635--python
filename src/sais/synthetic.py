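"""Synthetic feature streams with the statistical structure the model assumes.

Real inputs are frozen per-frame embeddings of surgical video: temporally
smooth, class-conditional in distribution, and correlated between the
appearance and motion modalities.  The generators here emulate exactly those
three properties — each category is a fixed random unit direction in feature
space scaled by a signal-to-noise ratio, frames carry stationary AR(1) noise,
and the motion stream mixes the appearance stream with independent noise —
so every pipeline stage can be exercised without any video data.  They make
no attempt to model photometric content, instrument kinematics or annotator
noise; conclusions drawn from them concern the machinery, not real surgery.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    APPEARANCE,
    MOTION,
    FrameFeatureSequence,
    VideoSample,
    sample_frame_indices,
    task_for_regime,
)
from .inference import EventInterval

__all__ = [
    "SyntheticConfig",
    "gen_clip",
    "gen_dataset",
    "gen_timeline",
    "gen_skill_outcome_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for synthetic feature streams.

    snr is the separation of class means in units of the per-frame noise
    standard deviation; temporal_smoothness is the AR(1) coefficient of the
    frame noise; modality_correlation mixes the motion stream with the
    appearance stream.  Durations and inter-event gaps are uniform ranges in
    seconds; the grammar is the ordered category motif that timelines repeat.
    """

    categories: tuple[str, ...] = ("hook", "clip", "cold_cut")
    dim: int = 32
    fps: float = 30.0
    snr: float = 5.0
    temporal_smoothness: float = 0.8
    modality_correlation: float = 0.7
    duration_range: tuple[float, float] = (2.0, 4.0)
    gap_range: tuple[float, float] = (2.5, 6.0)
    grammar: tuple[str, ...] | None = None  # None: repeat `categories` in order
    background_label: str = "background"
    seed: int = 0

    def __post_init__(self):
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not (0.0 <= self.temporal_smoothness < 1.0):
            raise ValueError("temporal_smoothness must lie in [0, 1)")
        if not (0.0 <= self.modality_correlation <= 1.0):
            raise ValueError("modality_correlation must lie in [0, 1]")
        if self.duration_range[0] <= 0 or self.duration_range[0] > self.duration_range[1]:
            raise ValueError("invalid duration_range")
        if len(self.categories) < 2:
            raise ValueError("need at least two categories")

    def class_means(self) -> np.ndarray:
        """Fixed unit direction per category, determined by the config seed."""
        rng = np.random.default_rng(self.seed)
        mu = rng.normal(size=(len(self.categories), self.dim))
        return mu / np.linalg.norm(mu, axis=1, keepdims=True)


def _ar1_noise(rng: np.random.Generator, t: int, d: int, a: float) -> np.ndarray:
    """Stationary AR(1) noise with unit marginal variance per coordinate."""
    x = np.empty((t, d))
    x[0] = rng.normal(size=d)
    scale = np.sqrt(1.0 - a * a)
    for i in range(1, t):
        x[i] = a * x[i - 1] + scale * rng.normal(size=d)
    return x


def _two_stream(rng, t, config: SyntheticConfig, signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = config.temporal_smoothness
    rho = config.modality_correlation
    app = signal + _ar1_noise(rng, t, config.dim, a)
    flow = rho * app + np.sqrt(1.0 - rho * rho) * _ar1_noise(rng, t, config.dim, a)
    return app, flow


def gen_clip(
    category: str,
    config: SyntheticConfig,
    seed: int,
    video_id: str = "synthetic",
    start_s: float = 0.0,
    duration_s: float | None = None,
) -> VideoSample:
    """One labelled clip at full frame rate.

    The appearance stream is the category's mean direction scaled by snr plus
    AR(1) noise; the motion stream mixes the appearance stream with
    independent noise according to the modality correlation.  The background
    label yields pure noise (zero signal), matching the inter-event stretches
    of generated timelines.
    """
    if category == config.background_label:
        signal: np.ndarray | float = 0.0
    elif category in config.categories:
        signal = config.snr * config.class_means()[config.categories.index(category)]
    else:
        raise ValueError(f"unknown category {category!r}")
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = rng.uniform(*config.duration_range)
    t = max(1, int(round(duration_s * config.fps)))
    app, flow = _two_stream(rng, t, config, signal)
    idx = np.arange(t)
    return VideoSample(
        video_id=video_id,
        start_s=start_s,
        end_s=start_s + duration_s,
        category=category,
        appearance=FrameFeatureSequence(APPEARANCE, app, idx, config.fps),
        motion=FrameFeatureSequence(MOTION, flow, idx, config.fps),
    )


def subsample_clip(sample: VideoSample, task: str, offset: int = 0) -> VideoSample:
    """Apply a task's frame-sampling rule to a full-rate clip."""
    t = sample.appearance.n_frames
    rel = sample_frame_indices(task, t) + offset
    rel = rel[rel < t]

    def take(seq):
        return FrameFeatureSequence(
            seq.modality, seq.vectors[rel], seq.frame_indices[rel], seq.fps
        )

    return VideoSample(
        sample.video_id, sample.start_s, sample.end_s, sample.category,
        take(sample.appearance), take(sample.motion),
    )


def gen_dataset(
    n_clips: int,
    config: SyntheticConfig,
    task: str = "gesture",
    clips_per_video: int = 10,
    include_background: bool = False,
) -> list[VideoSample]:
    """Balanced labelled clips grouped into synthetic case videos.

    Categories rotate round-robin so counts are balanced; consecutive clips
    share a video id (``clips_per_video`` each) so video-level splitting is
    meaningful.  Clips come already subsampled by the task's rule.  With
    ``include_background=True`` the rotation also includes pure-noise clips
    labelled with the background category, matching the idle stretches of
    generated timelines (used when training decoders for whole videos).
    """
    vocab = tuple(config.categories)
    if include_background:
        vocab = vocab + (config.background_label,)
    samples = []
    for i in range(n_clips):
        cat = vocab[i % len(vocab)]
        clip = gen_clip(
            cat, config, seed=config.seed + 1000 + i,
            video_id=f"vid{i // clips_per_video:03d}",
        )
        samples.append(subsample_clip(clip, task))
    return samples


def gen_timeline(
    duration_s: float,
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[EventInterval]]:
    """A whole synthetic video: feature streams plus ground-truth events.

    Events are laid down by walking the grammar motif (default: the
    categories in order, emulating the stereotyped hook → clip → cold-cut
    dissection pattern) with uniform gaps; between events the streams are
    pure noise.  ``seed`` varies the noise and event layout between videos
    while the class mean directions stay pinned to ``config.seed``.
    Returns (appearance, motion, truth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t_total = int(round(duration_s * config.fps))
    signal = np.zeros((t_total, config.dim))
    means = config.class_means()
    motif = config.grammar if config.grammar is not None else config.categories
    truth: list[EventInterval] = []
    t = rng.uniform(*config.gap_range)
    while True:
        placed_any = False
        for cat in motif:
            dur = rng.uniform(*config.duration_range)
            if t + dur > duration_s:
                break
            i0, i1 = int(round(t * config.fps)), int(round((t + dur) * config.fps))
            signal[i0:i1] = config.snr * means[config.categories.index(cat)]
            truth.append(EventInterval(cat, t, t + dur))
            placed_any = True
            t += dur + rng.uniform(*config.gap_range)
        if not placed_any:
            break
    app, flow = _two_stream(rng, t_total, config, signal)
    return app, flow, truth


def gen_skill_outcome_cohort(
    n: int,
    b0: float = 0.0,
    b1: float = 0.27,
    b2: float = 0.0,
    b3: float = 0.0,
    seed: int = 0,
    caseload_mean: float = 250.0,
    age_mean: float = 62.0,
    age_sd: float = 8.0,
) -> pd.DataFrame:
    """Simulated skill/outcome cohort for the adjusted logistic model.

    Z1 (high-skill probability) is uniform on [0, 1], Z2 (surgeon caseload)
    Poisson, Z3 (patient age, years) normal; the binary outcome Y is
    Bernoulli with logit ``b0 + b1 Z1 + b2 Z2 + b3 Z3``.  The default
    ``b1 = 0.27`` corresponds to an odds ratio of about 1.31 per unit of
    high-skill probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z1 = rng.uniform(0.0, 1.0, size=n)
    z2 = rng.poisson(caseload_mean, size=n).astype(float)
    z3 = rng.normal(age_mean, age_sd, size=n)
    logit = b0 + b1 * z1 + b2 * z2 + b3 * z3
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return pd.DataFrame(
        {"case_id": [f"case{i:05d}" for i in range(n)],
         "Z1": z1, "Z2": z2, "Z3": z3, "Y": y}
    )
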