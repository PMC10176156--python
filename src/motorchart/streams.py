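"""Stream processing: from raw frame-label streams to analysable playtime.

Order of operations in the wearable pipeline: the raw signal is segmented
into 2.3 s frames with 50% overlap (1.15 s hop), low-quality and carried
frames are masked, 10-minute super-segments of the frame-level label
distributions feed a binary free-play classifier, and only frames that are
good-quality, not carried, and playtime survive into feature computation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import config as cfg
from .config import MIN_PLAYTIME_HOURS, SUPER_SEGMENT_FRAMES, SUPER_SEGMENT_OVERLAP

logger = logging.getLogger("motorchart")


@dataclasses.dataclass
class RecordingSession:
    """One recording: identity, age at recording, and its frame stream."""

    recording_id: str
    subject_id: str
    dataset_tag: str
    age_months: float
    frames: pd.DataFrame
    hop_seconds: float = cfg.HOP_SECONDS

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError(f"recording {self.recording_id} has no frames")
        idx = self.frames["frame_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"frame_index not strictly increasing in {self.recording_id}")


@dataclasses.dataclass
class PlaytimeMask:
    """Per-frame playtime decision plus the retained playtime duration."""

    mask: np.ndarray  # boolean, aligned with the recording's frames
    retained_hours: float


# ---------------------------------------------------------------------------
# Frame grid
# ---------------------------------------------------------------------------

def frame_grid(n_samples: int, rate_hz: float, frame_seconds: float = cfg.FRAME_SECONDS,
               overlap_fraction: float = 0.5) -> list[tuple[int, int]]:
    """Sliding-window sample indices for fixed-length overlapping frames.

    At 52 Hz, 2.3 s frames are 120 samples with a 60-sample hop (50%
    overlap).  Frames tile ``[0, n_samples)`` maximally; a partial trailing
    frame is discarded.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    frame_len = int(round(frame_seconds * rate_hz))
    hop = int(round(frame_len * (1.0 - overlap_fraction)))
    if n_samples < frame_len:
        return []
    n_frames = (n_samples - frame_len) // hop + 1
    return [(i * hop, i * hop + frame_len) for i in range(n_frames)]


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def apply_quality_mask(frames: pd.DataFrame) -> pd.DataFrame:
    """Drop frames flagged as low signal quality."""
    kept = frames[frames["quality_flag"]]
    if len(kept) == 0:
        logger.warning("all %d frames removed by quality mask", len(frames))
    return kept


def apply_carried_mask(frames: pd.DataFrame) -> pd.DataFrame:
    """Drop frames where the infant is carried (caregiver-assisted movement)."""
    return frames[~frames["carried_flag"]]


# ---------------------------------------------------------------------------
# Super-segments and the playtime classifier
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SuperSegment:
    start_frame: int          # positional offset into the frame table
    end_frame: int            # exclusive
    features: np.ndarray      # [posture distribution ; movement distribution]
    short: bool = False       # recording shorter than one full window

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def _window_features(window: pd.DataFrame, postures, movements) -> np.ndarray:
    p = window["posture"].value_counts(normalize=True)
    m = window["movement"].value_counts(normalize=True)
    return np.concatenate([
        np.array([p.get(c, 0.0) for c in postures]),
        np.array([m.get(c, 0.0) for c in movements]),
    ])


def super_segments(frames: pd.DataFrame, window_frames: int = SUPER_SEGMENT_FRAMES,
                   overlap_fraction: float = SUPER_SEGMENT_OVERLAP,
                   postures=cfg.POSTURES, movements=cfg.MOVEMENTS) -> list[SuperSegment]:
    """Overlapping 10-minute windows of category-distribution features.

    Each window's feature vector is the empirical distribution of posture
    and of movement categories over its frames (each block sums to 1).  A
    recording shorter than one window yields a single truncated window
    flagged ``short``.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    n = len(frames)
    if n == 0:
        return []
    hop = max(int(round(window_frames * (1.0 - overlap_fraction))), 1)
    if n < window_frames:
        return [SuperSegment(0, n, _window_features(frames, postures, movements), short=True)]
    out = []
    for start in range(0, n - window_frames + 1, hop):
        window = frames.iloc[start:start + window_frames]
        out.append(SuperSegment(start, start + window_frames,
                                _window_features(window, postures, movements)))
    return out


@dataclasses.dataclass
class PlaytimeClassifier:
    """Regularized binary linear classifier on super-segment features."""

    model: LogisticRegression
    seed: int
    trained: bool = True

    @property
    def coef_(self) -> np.ndarray:
        return self.model.coef_


def train_playtime_classifier(features: np.ndarray, labels: np.ndarray,
                              seed: int = 0, C: float = 1.0) -> PlaytimeClassifier:
    """Fit the free-play detector on labelled super-segment features."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("playtime training needs both classes present")
    model = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    model.fit(np.asarray(features), labels)
    return PlaytimeClassifier(model=model, seed=seed)


def detect_playtime(windows: list[SuperSegment], classifier: PlaytimeClassifier,
                    n_frames: int, hop_seconds: float = cfg.HOP_SECONDS) -> PlaytimeMask:
    """Map per-window decisions back to frames.

    A frame is playtime iff the majority of the windows covering it are
    positive; ties count as positive.
    """
    if classifier is None or not getattr(classifier, "trained", False):
        raise ValueError("playtime classifier has not been trained")
    votes_pos = np.zeros(n_frames, dtype=np.int32)
    votes_all = np.zeros(n_frames, dtype=np.int32)
    if windows:
        preds = classifier.model.predict(np.vstack([w.features for w in windows]))
        for w, pred in zip(windows, preds):
            votes_all[w.start_frame:w.end_frame] += 1
            if pred:
                votes_pos[w.start_frame:w.end_frame] += 1
    mask = np.where(votes_all > 0, 2 * votes_pos >= votes_all, False)
    covered = np.flatnonzero(votes_all > 0)
    if len(covered) and covered[-1] < n_frames - 1:
        # trailing frames beyond the last full window inherit its decision
        mask[covered[-1] + 1:] = mask[covered[-1]]
    retained = float(mask.sum()) * hop_seconds / 3600.0
    return PlaytimeMask(mask=mask, retained_hours=retained)


# ---------------------------------------------------------------------------
# Analysis-frame selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FrameSelection:
    frames: pd.DataFrame
    retained_hours: float
    excluded: bool
    reason: str = ""


def select_analysis_frames(rec: RecordingSession,
                           playtime_mask: np.ndarray | None = None,
                           min_playtime_hours: float = MIN_PLAYTIME_HOURS) -> FrameSelection:
    """Frames passing quality AND not-carried AND playtime, with accounting.

    ``playtime_mask`` is a per-frame boolean from :func:`detect_playtime`;
    when absent, the stream's ``playtime_truth`` column is used (parental
    annotation surrogate).  Recordings retaining less than
    ``min_playtime_hours`` are excluded from feature computation and
    reported as such.  The three masks intersect, so application order is
    irrelevant.
    """
    frames = rec.frames
    if playtime_mask is None:
        play = frames["playtime_truth"].to_numpy()
    else:
        play = np.asarray(playtime_mask, dtype=bool)
        if len(play) != len(frames):
            raise ValueError("playtime mask length does not match frame count")
    keep = frames["quality_flag"].to_numpy() & ~frames["carried_flag"].to_numpy() & play
    selected = frames[keep]
    retained_hours = len(selected) * rec.hop_seconds / 3600.0
    if retained_hours < min_playtime_hours:
        return FrameSelection(frames=selected, retained_hours=retained_hours,
                              excluded=True,
                              reason=f"retained {retained_hours:.2f} h < "
                                     f"{min_playtime_hours:.2f} h minimum")
    return FrameSelection(frames=selected, retained_hours=retained_hours, excluded=False)


def cohort_sessions(cohort) -> list[RecordingSession]:
    """Wrap a generated/loaded cohort's streams as RecordingSession objects."""
    out = []
    for _, row in cohort.manifest.iterrows():
        out.append(RecordingSession(
            recording_id=row["recording_id"],
            subject_id=row["subject_id"],
            dataset_tag=row["dataset_tag"],
            age_months=float(row["age_months"]),
            frames=cohort.streams[row["recording_id"]],
        ))
    return out
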