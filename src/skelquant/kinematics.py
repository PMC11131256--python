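"""Bone vectors and per-frame skeleton parameters.

Six bone vectors are read off the seated subject's skeleton — right
shoulder (neck 1 → right shoulder 2), left shoulder (1 → 5), right hip
(mid-hip 8 → right hip 9), left hip (8 → 12), right thigh (right hip 9 →
right knee 10) and trunk (neck 1 → mid-hip 8).  The right thigh stands in
for both thighs because the left thigh is typically occluded by the right
one when the subject sits facing the camera.

Each non-trunk bone contributes two per-frame scalars:

* its length  ``l = sqrt(dx^2 + dy^2)``  in pixels, and
* its inclination  ``theta = |atan(dy/dx)|``  in degrees, folded into
  [0, 90] (a vertical bone, dx = 0, is defined as 90 — the continuous
  limit).

The trunk contributes only an angle, kept on the half-circle [0, 180):
``phi = atan(dy/dx)`` in degrees with ``phi + 180`` taken when negative,
so left- and right-leaning postures remain distinguishable.  That yields
the 11 skeleton-parameter time series (5 lengths + 6 angles) that feed the
variance descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import SkeletonFrame, SkeletonSequence


@dataclass(frozen=True)
class BoneSpec:
    name: str
    from_joint: int
    to_joint: int


#: The six bones, in canonical order.
BONES: tuple[BoneSpec, ...] = (
    BoneSpec("right_shoulder", 1, 2),
    BoneSpec("left_shoulder", 1, 5),
    BoneSpec("right_hip", 8, 9),
    BoneSpec("left_hip", 8, 12),
    BoneSpec("right_thigh", 9, 10),
    BoneSpec("trunk", 1, 8),
)
BONES_BY_NAME = {b.name: b for b in BONES}

LENGTH_PARAMETERS = ("l_1_2", "l_1_5", "l_8_9", "l_8_12", "l_9_10")
ANGLE_PARAMETERS = ("th_1_2", "th_1_5", "th_8_9", "th_8_12", "th_9_10", "th_8_1")
#: Canonical order of the 11 skeleton parameters.
PARAMETERS = LENGTH_PARAMETERS + ANGLE_PARAMETERS

#: parameter name -> (bone, kind); the trunk angle is conventionally
#: written th_8_1 although the underlying vector runs from neck to mid-hip.
PARAMETER_BONES: dict[str, tuple[BoneSpec, str]] = {
    "l_1_2": (BONES[0], "length"),
    "l_1_5": (BONES[1], "length"),
    "l_8_9": (BONES[2], "length"),
    "l_8_12": (BONES[3], "length"),
    "l_9_10": (BONES[4], "length"),
    "th_1_2": (BONES[0], "angle"),
    "th_1_5": (BONES[1], "angle"),
    "th_8_9": (BONES[2], "angle"),
    "th_8_12": (BONES[3], "angle"),
    "th_9_10": (BONES[4], "angle"),
    "th_8_1": (BONES[5], "trunk_angle"),
}


def bone_vector(frame: SkeletonFrame, spec: BoneSpec) -> tuple[float, float] | None:
    """Displacement (dx, dy) of a bone in one frame; None if a joint is missing."""
    ci = frame.confidence[spec.from_joint]
    cj = frame.confidence[spec.to_joint]
    if ci == 0 or cj == 0:
        return None
    dx = frame.xy[spec.to_joint, 0] - frame.xy[spec.from_joint, 0]
    dy = frame.xy[spec.to_joint, 1] - frame.xy[spec.from_joint, 1]
    return float(dx), float(dy)


def bone_length(v: tuple[float, float]) -> float:
    """Euclidean length of a bone displacement, in pixels."""
    return float(np.hypot(v[0], v[1]))


def bone_angle(v: tuple[float, float]) -> float:
    """Unsigned bone inclination in degrees, in [0, 90].

    A zero vector has no direction and is rejected: coincident-joint
    detection glitches must not masquerade as an angle of 0.
    """
    dx, dy = v
    if dx == 0 and dy == 0:
        raise ValueError("angle of a zero-length bone vector is undefined")
    return float(np.degrees(np.arctan2(abs(dy), abs(dx))))


def trunk_angle(v: tuple[float, float]) -> float:
    """Signed trunk inclination folded to [0, 180) degrees."""
    dx, dy = v
    if dx == 0 and dy == 0:
        raise ValueError("angle of a zero-length bone vector is undefined")
    return float(np.degrees(np.arctan2(dy, dx)) % 180.0)


@dataclass
class ParameterSeriesSet:
    """The 11 skeleton-parameter time series of one subject.

    ``values`` is (T, 11) in :data:`PARAMETERS` order (pixels for lengths,
    degrees for angles); ``valid`` marks frames whose endpoint joints were
    both detected (and, for angles, non-coincident).  Invalid entries hold
    NaN.
    """

    subject_id: str
    label: str
    values: np.ndarray
    valid: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(PARAMETERS):
            raise ValueError(f"values must have shape (T, {len(PARAMETERS)})")
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match values' shape")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def series(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = PARAMETERS.index(name)
        return self.values[:, i], self.valid[:, i]

    def to_long_frame(self) -> pd.DataFrame:
        T = self.n_frames
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_id, T * len(PARAMETERS)),
                "frame": np.repeat(np.arange(T), len(PARAMETERS)),
                "parameter": np.tile(np.array(PARAMETERS), T),
                "value": self.values.ravel(),
                "valid": self.valid.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# label: {self.label}\n")
            fh.write(f"# frame_rate: {self.frame_rate!r}\n")
            self.to_long_frame().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path, label: str | None = None) -> "ParameterSeriesSet":
        from .pose_io import _read_csv_metadata

        meta = _read_csv_metadata(path)
        df = pd.read_csv(path, comment="#")
        required = {"subject_id", "frame", "parameter", "value", "valid"}
        if missing := required - set(df.columns):
            raise ValueError(f"{path} is missing columns: {sorted(missing)}")
        subjects = df["subject_id"].unique()
        if len(subjects) != 1:
            raise ValueError("parameter CSV must hold exactly one subject")
        wide_v = df.pivot(index="frame", columns="parameter", values="value")
        wide_m = df.pivot(index="frame", columns="parameter", values="valid")
        wide_v = wide_v[list(PARAMETERS)]
        wide_m = wide_m[list(PARAMETERS)]
        return cls(
            subject_id=str(subjects[0]),
            label=label or meta.get("label", "non-ADHD"),
            values=wide_v.to_numpy(dtype=float),
            valid=wide_m.to_numpy(dtype=bool),
            frame_rate=float(meta.get("frame_rate", 30.0)),
        )


def compute_parameter_series(
    seq: SkeletonSequence, truncate_minutes: float | None = 4.0
) -> ParameterSeriesSet:
    """Compute the 11 parameter series from a skeleton sequence.

    Only the initial ``truncate_minutes`` of recording enter the analysis
    (default 4 minutes: recordings are 4–6 minutes long and trimming to a
    common duration avoids biasing variance comparisons); pass ``None`` to
    keep everything.
    """
    T = seq.n_frames
    if truncate_minutes is not None:
        T = min(T, int(truncate_minutes * 60.0 * seq.frame_rate))
        if T < 1:
            raise ValueError("truncation leaves no frames")
    xy = seq.xy[:T]
    conf = seq.confidence[:T]

    values = np.full((T, len(PARAMETERS)), np.nan)
    valid = np.zeros((T, len(PARAMETERS)), dtype=bool)
    for col, name in enumerate(PARAMETERS):
        bone, kind = PARAMETER_BONES[name]
        i, j = bone.from_joint, bone.to_joint
        ok = (conf[:, i] > 0) & (conf[:, j] > 0)
        dx = xy[:, j, 0] - xy[:, i, 0]
        dy = xy[:, j, 1] - xy[:, i, 1]
        if kind == "length":
            vals = np.hypot(dx, dy)
        else:
            nonzero = (dx != 0) | (dy != 0)
            ok = ok & nonzero
            with np.errstate(invalid="ignore"):
                if kind == "angle":
                    vals = np.degrees(np.arctan2(np.abs(dy), np.abs(dx)))
                else:  # trunk_angle
                    vals = np.degrees(np.arctan2(dy, dx)) % 180.0
        values[ok, col] = vals[ok]
        valid[:, col] = ok
    return ParameterSeriesSet(
        subject_id=seq.subject_id,
        label=seq.label,
        values=values,
        valid=valid,
        frame_rate=seq.frame_rate,
    )
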