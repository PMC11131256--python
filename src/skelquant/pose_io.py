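"""Reading and writing pose-estimation output.

Consumes the per-frame JSON emitted by OpenPose-style 2-D pose estimators
(one file per frame, a ``"people"`` list, each person a flat
``pose_keypoints_2d`` list of 75 numbers: x1, y1, c1, ..., x25, y25, c25),
resolves multi-person frames to the single tracked subject, repairs short
detection dropouts, and round-trips sequences through a long-format CSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .skeleton import N_JOINTS, SkeletonSequence

__all__ = [
    "read_openpose_sequence",
    "select_primary_person",
    "repair_missing_joints",
    "write_sequence_csv",
    "read_sequence_csv",
    "write_openpose_json",
]

_FRAME_NUMBER_RE = re.compile(r"(\d+)\D*$")

CSV_COLUMNS = ("subject_id", "frame", "joint", "x", "y", "confidence")


def _frame_number(path: Path) -> int:
    m = _FRAME_NUMBER_RE.search(path.stem)
    if m is None:
        raise ValueError(f"cannot extract a frame number from file name {path.name!r}")
    return int(m.group(1))


def _parse_people(path: Path) -> list[np.ndarray]:
    """Extract each detected person as a (25, 3) array from one JSON file."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {path.name}: {exc}") from exc

    if isinstance(data, dict):
        raw_people = data.get("people", [])
    else:
        raw_people = data
    people: list[np.ndarray] = []
    for person in raw_people:
        if isinstance(person, dict):
            keypoints = person.get("pose_keypoints_2d")
            if keypoints is None:
                raise ValueError(f"person without pose_keypoints_2d in {path.name}")
        else:
            keypoints = person
        kp = np.asarray(keypoints, dtype=float).ravel()
        if kp.size == 0 or kp.size % 75 != 0:
            raise ValueError(
                f"keypoint list length {kp.size} in {path.name} is not a multiple of 75"
            )
        # a flat list may concatenate several people
        people.extend(kp.reshape(-1, N_JOINTS, 3))
    return people


def select_primary_person(
    candidates: Sequence[np.ndarray],
    previous: np.ndarray | None = None,
) -> np.ndarray:
    """Pick the tracked subject among the people detected in one frame.

    With a usable previous-frame skeleton the candidate minimising the mean
    Euclidean distance over jointly detected joints wins (nearest-neighbour
    tracking — adequate for a seated subject).  Without one, the candidate
    with the largest total confidence wins.  Ties break to the lowest
    candidate index; the rule is fully deterministic.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    cands = [np.asarray(c, dtype=float) for c in candidates]
    for c in cands:
        if c.shape != (N_JOINTS, 3):
            raise ValueError(f"candidate must have shape ({N_JOINTS}, 3)")

    if previous is not None:
        previous = np.asarray(previous, dtype=float)
        prev_ok = previous[:, 2] > 0
        if prev_ok.any():
            dists = np.full(len(cands), np.inf)
            for idx, cand in enumerate(cands):
                both = prev_ok & (cand[:, 2] > 0)
                if both.any():
                    d = np.linalg.norm(cand[both, :2] - previous[both, :2], axis=1)
                    dists[idx] = d.mean()
            if np.isfinite(dists).any():
                return cands[int(np.argmin(dists))]
    totals = [c[:, 2].sum() for c in cands]
    return cands[int(np.argmax(totals))]


def read_openpose_sequence(
    path: str | Path,
    subject_id: str,
    label: str,
    frame_rate: float = 30.0,
    frame_size: tuple[int, int] = (1280, 720),
) -> SkeletonSequence:
    """Read a directory of per-frame pose JSON files into one sequence.

    Files sort into frame order by the last run of digits in their stem.
    Frames with no detected person become frames of 25 missing joints;
    multi-person frames are resolved with :func:`select_primary_person`.
    """
    directory = Path(path)
    files = sorted(directory.glob("*.json"), key=lambda p: (_frame_number(p), p.name))
    if not files:
        raise ValueError(f"no JSON files found in {directory}")
    numbers = [_frame_number(p) for p in files]
    if len(set(numbers)) != len(numbers):
        dupes = sorted({n for n in numbers if numbers.count(n) > 1})
        raise ValueError(f"duplicate frame numbers in {directory}: {dupes[:5]}")

    T = len(files)
    xy = np.zeros((T, N_JOINTS, 2))
    conf = np.zeros((T, N_JOINTS))
    previous: np.ndarray | None = None
    for t, fpath in enumerate(files):
        people = _parse_people(fpath)
        if people:
            chosen = select_primary_person(people, previous)
            xy[t] = chosen[:, :2]
            conf[t] = chosen[:, 2]
            previous = chosen
        # else: stays a frame of 25 missing joints; tracking keeps the last
        # usable skeleton as reference across the gap
    return SkeletonSequence(
        subject_id=subject_id,
        label=label,
        xy=xy,
        confidence=conf,
        frame_size=frame_size,
        frame_rate=frame_rate,
        frame_indices=np.array(numbers),
    )


def repair_missing_joints(
    seq: SkeletonSequence, max_gap: int = 15
) -> tuple[SkeletonSequence, pd.DataFrame]:
    """Fill short per-joint detection dropouts by linear interpolation.

    For each joint, interior runs of missing frames no longer than
    ``max_gap`` are filled per-coordinate between the flanking detections;
    the filled confidence is the smaller flank.  Longer runs and runs
    touching either end of the sequence stay missing.  The default of 15
    frames (0.5 s at 30 Hz) bridges blink-length dropouts without
    fabricating movement.  Returns the repaired sequence and a per-joint
    report of filled / unfilled frame counts.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    xy = seq.xy.copy()
    conf = seq.confidence.copy()
    T = seq.n_frames
    rows = []
    for j in range(N_JOINTS):
        present = conf[:, j] > 0
        n_missing = int((~present).sum())
        filled = 0
        if n_missing and present.any():
            idx = np.flatnonzero(present)
            # iterate over interior gaps between consecutive detections
            for a, b in zip(idx[:-1], idx[1:]):
                gap = b - a - 1
                if 0 < gap <= max_gap:
                    ts = np.arange(a + 1, b)
                    w = (ts - a) / (b - a)
                    xy[ts, j, 0] = xy[a, j, 0] + w * (xy[b, j, 0] - xy[a, j, 0])
                    xy[ts, j, 1] = xy[a, j, 1] + w * (xy[b, j, 1] - xy[a, j, 1])
                    conf[ts, j] = min(conf[a, j], conf[b, j])
                    filled += gap
        rows.append(
            {
                "joint": j,
                "n_missing": n_missing,
                "n_filled": filled,
                "n_unfilled": n_missing - filled,
            }
        )
    repaired = SkeletonSequence(
        subject_id=seq.subject_id,
        label=seq.label,
        xy=xy,
        confidence=conf,
        frame_size=seq.frame_size,
        frame_rate=seq.frame_rate,
        frame_indices=seq.frame_indices.copy(),
    )
    return repaired, pd.DataFrame(rows)


def write_sequence_csv(seq: SkeletonSequence, path: str | Path) -> None:
    """Write a sequence as long-format CSV (lossless round trip).

    Columns: subject_id, frame, joint, x, y, confidence.  Sequence-level
    metadata travels in ``#``-prefixed header comment lines.
    """
    T = seq.n_frames
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(seq.subject_id, T * N_JOINTS),
            "frame": np.repeat(seq.frame_indices, N_JOINTS),
            "joint": np.tile(np.arange(N_JOINTS), T),
            "x": seq.xy[:, :, 0].ravel(),
            "y": seq.xy[:, :, 1].ravel(),
            "confidence": seq.confidence.ravel(),
        }
    )
    with open(path, "w", newline="") as fh:
        fh.write(f"# label: {seq.label}\n")
        fh.write(f"# frame_rate: {seq.frame_rate!r}\n")
        fh.write(f"# frame_width: {seq.frame_size[0]}\n")
        fh.write(f"# frame_height: {seq.frame_size[1]}\n")
        df.to_csv(fh, index=False)


def _read_csv_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, value = line.lstrip("#").split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_sequence_csv(
    path: str | Path,
    label: str | None = None,
    frame_rate: float | None = None,
    frame_size: tuple[int, int] | None = None,
) -> SkeletonSequence:
    """Read a long-format sequence CSV written by :func:`write_sequence_csv`.

    Metadata arguments override whatever the file header carries.
    """
    path = Path(path)
    meta = _read_csv_metadata(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path} is empty") from exc
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path} is missing columns: {sorted(missing_cols)}")
    subjects = df["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"{path} must hold exactly one subject, found {len(subjects)}")

    df = df.sort_values(["frame", "joint"], kind="stable")
    frames = df["frame"].unique()
    T = len(frames)
    if len(df) != T * N_JOINTS or not np.array_equal(
        df["joint"].to_numpy().reshape(T, N_JOINTS), np.tile(np.arange(N_JOINTS), (T, 1))
    ):
        raise ValueError(f"{path} must contain all {N_JOINTS} joints for every frame")

    if label is None:
        label = meta.get("label")
        if label is None:
            raise ValueError(f"{path} has no label metadata; pass label= explicitly")
    if frame_rate is None:
        frame_rate = float(meta.get("frame_rate", 30.0))
    if frame_size is None:
        frame_size = (
            int(meta.get("frame_width", 1280)),
            int(meta.get("frame_height", 720)),
        )
    return SkeletonSequence(
        subject_id=str(subjects[0]),
        label=label,
        xy=df[["x", "y"]].to_numpy().reshape(T, N_JOINTS, 2),
        confidence=df["confidence"].to_numpy().reshape(T, N_JOINTS),
        frame_size=frame_size,
        frame_rate=frame_rate,
        frame_indices=frames,
    )


def write_openpose_json(
    seq: SkeletonSequence,
    directory: str | Path,
    extra_people: dict[int, list[np.ndarray]] | None = None,
) -> None:
    """Write a sequence as per-frame pose-estimator JSON files.

    ``extra_people`` maps a frame position (0-based within the sequence) to
    additional (25, 3) detections written after the subject — used to
    emulate a parent or clinician entering the camera view.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    extra_people = extra_people or {}
    for t in range(seq.n_frames):
        people = []
        joints = np.column_stack([seq.xy[t], seq.confidence[t]])
        # pose estimators emit all-zero triples for undetected joints
        joints[seq.confidence[t] == 0] = 0.0
        if (joints[:, 2] > 0).any():
            people.append({"pose_keypoints_2d": joints.ravel().tolist()})
        for extra in extra_people.get(t, []):
            people.append(
                {"pose_keypoints_2d": np.asarray(extra, dtype=float).ravel().tolist()}
            )
        payload = {"version": 1.3, "people": people}
        with open(directory / f"frame_{seq.frame_indices[t]:012d}_keypoints.json", "w") as fh:
            json.dump(payload, fh)
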