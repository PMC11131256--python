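"""Core skeleton data model.

A subject is represented per frame by the 25-keypoint body model produced
by common 2-D pose estimators (BODY_25): each joint carries pixel
coordinates ``(x, y)`` — origin at the top-left image corner, x rightward,
y downward — and a detection confidence in ``[0, 1]``.  A confidence of
exactly zero marks a *missing* joint; its coordinates carry no meaning and
must never enter any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_JOINTS = 25

#: BODY_25 keypoint order.
JOINT_NAMES = (
    "nose",            # 0
    "neck",            # 1
    "right_shoulder",  # 2
    "right_elbow",     # 3
    "right_wrist",     # 4
    "left_shoulder",   # 5
    "left_elbow",      # 6
    "left_wrist",      # 7
    "mid_hip",         # 8
    "right_hip",       # 9
    "right_knee",      # 10
    "right_ankle",     # 11
    "left_hip",        # 12
    "left_knee",       # 13
    "left_ankle",      # 14
    "right_eye",       # 15
    "left_eye",        # 16
    "right_ear",       # 17
    "left_ear",        # 18
    "left_big_toe",    # 19
    "left_small_toe",  # 20
    "left_heel",       # 21
    "right_big_toe",   # 22
    "right_small_toe", # 23
    "right_heel",      # 24
)

ADHD = "ADHD"
NON_ADHD = "non-ADHD"
LABELS = (ADHD, NON_ADHD)


def validate_label(label: str) -> str:
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    return label


@dataclass
class SkeletonFrame:
    """One video frame's detected skeleton.

    ``joints`` is a ``(25, 3)`` float array of ``(x, y, confidence)`` rows
    in BODY_25 order.  ``frame_size`` is ``(Nx, Ny)`` in pixels.
    """

    frame_index: int
    joints: np.ndarray
    frame_size: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.shape != (N_JOINTS, 3):
            raise ValueError(
                f"joints must have shape ({N_JOINTS}, 3), got {self.joints.shape}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def xy(self) -> np.ndarray:
        return self.joints[:, :2]

    @property
    def confidence(self) -> np.ndarray:
        return self.joints[:, 2]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of undetected joints (confidence == 0)."""
        return self.joints[:, 2] == 0.0


@dataclass
class SkeletonSequence:
    """One subject's ordered skeleton frames.

    Stored columnar for vectorised downstream math: ``xy`` is
    ``(T, 25, 2)``, ``confidence`` is ``(T, 25)``.  ``frame_indices`` are
    strictly increasing (0-based; gaps allowed when the recording skipped
    frames).
    """

    subject_id: str
    label: str
    xy: np.ndarray
    confidence: np.ndarray
    frame_size: tuple[int, int] = (1280, 720)
    frame_rate: float = 30.0
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        validate_label(self.label)
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_JOINTS, 2):
            raise ValueError(f"xy must have shape (T, {N_JOINTS}, 2)")
        T = self.xy.shape[0]
        if T < 1:
            raise ValueError("a sequence needs at least one frame")
        if self.confidence.shape != (T, N_JOINTS):
            raise ValueError(f"confidence must have shape (T, {N_JOINTS})")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frame_indices is None:
            self.frame_indices = np.arange(T)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if self.frame_indices.shape != (T,):
                raise ValueError("frame_indices must have shape (T,)")
            if T > 1 and not np.all(np.diff(self.frame_indices) > 0):
                raise ValueError("frame_indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """(T, 25) boolean mask of undetected joints."""
        return self.confidence == 0.0

    def frame(self, t: int) -> SkeletonFrame:
        joints = np.column_stack([self.xy[t], self.confidence[t]])
        return SkeletonFrame(int(self.frame_indices[t]), joints, self.frame_size)

    @classmethod
    def from_frames(
        cls,
        frames: list[SkeletonFrame],
        subject_id: str,
        label: str,
        frame_rate: float = 30.0,
    ) -> "SkeletonSequence":
        if not frames:
            raise ValueError("need at least one frame")
        sizes = {f.frame_size for f in frames}
        if len(sizes) != 1:
            raise ValueError("all frames must share the same frame size")
        return cls(
            subject_id=subject_id,
            label=label,
            xy=np.stack([f.xy for f in frames]),
            confidence=np.stack([f.confidence for f in frames]),
            frame_size=frames[0].frame_size,
            frame_rate=frame_rate,
            frame_indices=np.array([f.frame_index for f in frames]),
        )

    def equals(self, other: "SkeletonSequence") -> bool:
        """Exact equality of all fields (missing-joint coordinates included)."""
        return (
            self.subject_id == other.subject_id
            and self.label == other.label
            and self.frame_size == tuple(other.frame_size)
            and self.frame_rate == other.frame_rate
            and np.array_equal(self.frame_indices, other.frame_indices)
            and np.array_equal(self.xy, other.xy)
            and np.array_equal(self.confidence, other.confidence)
        )
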