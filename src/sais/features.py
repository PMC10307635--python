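"""Per-frame feature streams: containers, frame sampling and modality pairing.

Videos are represented offline by per-frame embedding matrices (one row per
frame, ``D`` columns), one matrix per modality — appearance ("RGB") and motion
(optical flow).  This module defines the in-memory containers for labelled
clips, the task-specific frame-sampling rules, the pairing rule that aligns
motion frames with appearance frames, and an HDF5-backed store for whole-video
feature matrices keyed by video id and modality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

APPEARANCE = "appearance"
MOTION = "motion"
MODALITIES = (APPEARANCE, MOTION)

#: tasks with distinct frame-sampling rules
GESTURE = "gesture"
SUBPHASE_OR_SKILL = "subphase_or_skill"


class FeatureNotFoundError(KeyError):
    """Requested (video id, modality) pair is absent from a feature store."""


@dataclass(frozen=True)
class FrameFeatureSequence:
    """Ordered per-frame feature vectors for one modality of one clip.

    Parameters
    ----------
    modality : {"appearance", "motion"}
    vectors : (T, D) array
        One embedding per retained frame.  Padded rows must be all-zero.
    frame_indices : (T,) int array
        Strictly increasing indices into the source video.
    fps : float
        Frame rate of the source video (frames / second).
    valid_mask : (T,) bool array
        False marks padding rows appended for batching.
    """

    modality: str
    vectors: np.ndarray
    frame_indices: np.ndarray
    fps: float
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        vectors = np.asarray(self.vectors, dtype=np.float64)
        idx = np.asarray(self.frame_indices, dtype=np.int64)
        mask = self.valid_mask
        mask = np.ones(len(idx), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "frame_indices", idx)
        object.__setattr__(self, "valid_mask", mask)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if vectors.ndim != 2 or len(idx) != vectors.shape[0] or len(mask) != vectors.shape[0]:
            raise ValueError("vectors, frame_indices and valid_mask must agree on T")
        valid_idx = idx[mask]
        if len(valid_idx) and (np.any(np.diff(valid_idx) <= 0) or valid_idx[0] < 0):
            raise ValueError("frame_indices must be strictly increasing and non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(vectors[~mask] != 0.0):
            raise ValueError("padded rows must be all-zero")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def timestamps(self, start_s: float = 0.0) -> np.ndarray:
        """Seconds of each frame relative to the source video start."""
        return start_s + self.frame_indices / self.fps

    def pad_to(self, n: int) -> "FrameFeatureSequence":
        """Append all-zero padding rows (valid_mask False) up to length ``n``."""
        extra = n - self.n_frames
        if extra < 0:
            raise ValueError("cannot pad to a shorter length")
        if extra == 0:
            return self
        last = int(self.frame_indices[self.valid_mask][-1]) if self.valid_mask.any() else -1
        return replace(
            self,
            vectors=np.vstack([self.vectors, np.zeros((extra, self.dim))]),
            frame_indices=np.concatenate([self.frame_indices, last + 1 + np.arange(extra)]),
            valid_mask=np.concatenate([self.valid_mask, np.zeros(extra, dtype=bool)]),
        )


@dataclass(frozen=True)
class VideoSample:
    """A labelled clip: paired appearance/motion streams plus its annotation."""

    video_id: str
    start_s: float
    end_s: float
    category: str | None
    appearance: FrameFeatureSequence | None
    motion: FrameFeatureSequence | None

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.appearance is None and self.motion is None:
            raise ValueError("at least one modality stream is required")

    def stream(self, modality: str) -> FrameFeatureSequence | None:
        return self.appearance if modality == APPEARANCE else self.motion


@dataclass(frozen=True)
class FeatureExtractionConfig:
    """Geometry of the (external) frozen frame-feature extractor."""

    frame_size: int = 224
    patch_size: int = 16
    dim: int = 384
    flow_dt: float = 0.5

    def __post_init__(self):
        if self.frame_size % self.patch_size != 0:
            raise ValueError("frame_size must be divisible by patch_size")
        if self.dim <= 0 or self.flow_dt <= 0:
            raise ValueError("dim and flow_dt must be positive")


class FrameFeatureExtractor(Protocol):
    """Adapter seam for turning raw video into per-frame feature matrices.

    Implementations (e.g. a frozen self-supervised ViT for appearance, an
    optical-flow network for motion) are intentionally out of scope here; any
    callable mapping a video path to a (T_total, D) matrix plus fps fits.
    """

    def __call__(self, video_path: str | Path, modality: str) -> tuple[np.ndarray, float]: ...


# ---------------------------------------------------------------------------
# frame sampling
# ---------------------------------------------------------------------------

def sample_frame_indices(task: str, n_total_frames: int) -> np.ndarray:
    """Select frame indices for a clip according to the task's sampling rule.

    Gesture classification uses ten equally spaced frames (a 90-frame clip
    yields ``[0, 9, 18, ..., 81]``); subphase recognition and skill assessment
    use every tenth frame (``[0, 10, 20, ...]``).  Clips shorter than ten
    frames fall back to all frames for the gesture rule.
    """
    if n_total_frames < 1:
        raise ValueError("n_total_frames must be >= 1")
    if task == GESTURE:
        if n_total_frames < 10:
            logger.warning(
                "gesture sampling needs >= 10 frames, got %d; using all frames",
                n_total_frames,
            )
            return np.arange(n_total_frames, dtype=np.int64)
        spacing = (n_total_frames - 1) // 9
        return np.arange(10, dtype=np.int64) * spacing
    if task == SUBPHASE_OR_SKILL:
        return np.arange(0, n_total_frames, 10, dtype=np.int64)
    raise ValueError(f"unknown task {task!r}")


def pair_motion_frames(
    rgb_indices: Sequence[int],
    fps: float,
    flow_dt: float,
    n_total_frames: int,
) -> list[tuple[int, int]]:
    """Pair each appearance frame with the frame ``flow_dt`` seconds later.

    Motion (optical-flow) features are computed from image pairs separated by
    ``flow_dt`` seconds, i.e. ``round(fps * flow_dt)`` frames.  One pair is
    aligned with each appearance frame so the two streams overlap in time; a
    pair whose second frame would fall beyond the clip is anchored backwards
    instead, and clips shorter than ``flow_dt`` yield no pairs.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if flow_dt <= 0:
        raise ValueError("flow_dt must be positive")
    sep = int(round(fps * flow_dt))
    if n_total_frames <= sep:
        warnings.warn(
            f"clip of {n_total_frames} frames is shorter than the {flow_dt}s flow pairing span",
            stacklevel=2,
        )
        return []
    pairs = []
    for i in map(int, rgb_indices):
        if i + sep < n_total_frames:
            pairs.append((i, i + sep))
        elif i - sep >= 0:
            pairs.append((i - sep, i))
    return pairs


# ---------------------------------------------------------------------------
# feature store
# ---------------------------------------------------------------------------

class FeatureStore:
    """HDF5-backed store of whole-video feature matrices.

    Layout: one group per video id containing one ``(T_total, D)`` dataset per
    modality; the frame rate is stored as an ``fps`` attribute on the group.
    Matrices are written once, offline, and read back bit-exactly.
    """

    def __init__(self, path: str | Path, mode: str = "a"):
        self.path = Path(path)
        self._file = h5py.File(self.path, mode)

    def close(self) -> None:
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def store(self, video_id: str, modality: str, matrix: np.ndarray, fps: float | None = None) -> None:
        matrix = np.asarray(matrix)
        if matrix.ndim != 2:
            raise ValueError("feature matrix must be T_total x D")
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        grp = self._file.require_group(video_id)
        if modality in grp:
            del grp[modality]
        grp.create_dataset(modality, data=matrix)
        if fps is not None:
            grp.attrs["fps"] = float(fps)

    def load(self, video_id: str, modality: str) -> np.ndarray:
        if video_id not in self._file or modality not in self._file[video_id]:
            raise FeatureNotFoundError(
                f"no features stored for video {video_id!r}, modality {modality!r}"
            )
        return self._file[video_id][modality][...]

    def fps(self, video_id: str) -> float:
        if video_id not in self._file:
            raise FeatureNotFoundError(f"no features stored for video {video_id!r}")
        return float(self._file[video_id].attrs["fps"])

    def video_ids(self) -> list[str]:
        return sorted(self._file.keys())


def store_features(container: FeatureStore, video_id: str, modality: str,
                   matrix: np.ndarray, fps: float | None = None) -> None:
    container.store(video_id, modality, matrix, fps=fps)


def load_features(container: FeatureStore, video_id: str, modality: str) -> np.ndarray:
    return container.load(video_id, modality)


# ---------------------------------------------------------------------------
# annotations and clip extraction
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["video_id", "start_s", "end_s", "category"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df[ANNOTATION_COLUMNS]


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def task_for_regime(regime: str) -> str:
    """Map an inference regime to its frame-sampling task."""
    if regime == "gesture":
        return GESTURE
    if regime in ("subphase", "skill"):
        return SUBPHASE_OR_SKILL
    raise ValueError(f"unknown regime {regime!r}")


def extract_clip(
    appearance: np.ndarray,
    motion: np.ndarray,
    fps: float,
    video_id: str,
    start_s: float,
    end_s: float,
    task: str,
    category: str | None = None,
    offset: int = 0,
) -> VideoSample:
    """Cut a labelled clip out of whole-video feature matrices.

    The half-open window ``[start_s, end_s)`` is converted to frame indices,
    the task's sampling rule picks frames inside the window, and ``offset``
    shifts the start frame (used by test-time augmentation); shifted indices
    beyond the window are dropped.
    """
    t_total = appearance.shape[0]
    i0 = int(round(start_s * fps))
    i1 = min(int(round(end_s * fps)), t_total)
    n = i1 - i0
    if n < 1:
        raise ValueError(f"window [{start_s}, {end_s}) holds no frames at {fps} fps")
    rel = sample_frame_indices(task, n) + offset
    rel = rel[rel < n]
    idx = i0 + rel

    def seq(mat, modality):
        return FrameFeatureSequence(
            modality=modality, vectors=mat[idx], frame_indices=idx, fps=fps
        )

    return VideoSample(
        video_id=video_id,
        start_s=start_s,
        end_s=end_s,
        category=category,
        appearance=seq(appearance, APPEARANCE),
        motion=seq(motion, MOTION),
    )
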