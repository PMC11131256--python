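"""Averaged-variance feature descriptors and the cohort dataset matrix.

Restlessness shows up as frame-to-frame fluctuation of the skeleton
parameters.  Each of the 11 parameter series is summarised by one scalar:
the series is cut into K = floor(T / R) disjoint windows of R frames
(window k covers frames (k-1)R+1 ... kR; the trailing remainder is
discarded), the unbiased sample variance (denominator R - 1) is computed
within each window, and the K window variances are averaged.  Windowing
makes the descriptor sensitive to short fidgeting bouts while slow
posture drift across the recording contributes little.

Stacking the 11 descriptors plus the group label over all subjects gives
the dataset matrix (one row per subject, 12 columns) consumed by the
statistical comparison, cutoff and classification analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import PARAMETERS, ParameterSeriesSet
from .skeleton import validate_label

#: Descriptor column names, aligned with kinematics.PARAMETERS.
DESCRIPTORS = tuple(f"var_{p}" for p in PARAMETERS)

#: Human-readable descriptor names.
DESCRIPTOR_TITLES = {
    "var_l_1_2": "Right shoulder length",
    "var_l_1_5": "Left shoulder length",
    "var_l_8_9": "Right hip length",
    "var_l_8_12": "Left hip length",
    "var_l_9_10": "Thigh length",
    "var_th_1_2": "Right shoulder angle",
    "var_th_1_5": "Left shoulder angle",
    "var_th_8_9": "Right hip angle",
    "var_th_8_12": "Left hip angle",
    "var_th_9_10": "Thigh angle",
    "var_th_8_1": "Trunk angle",
}

LABEL_COLUMN = "label"


class UnusableFeatureError(ValueError):
    """A descriptor cannot be computed (series too short or no usable window)."""


class UnusableSubjectError(ValueError):
    """A subject is dropped because at least one descriptor is unusable."""

    def __init__(self, subject_id: str, reasons: dict[str, str]):
        self.subject_id = subject_id
        self.reasons = reasons
        details = "; ".join(f"{k}: {v}" for k, v in reasons.items())
        super().__init__(f"subject {subject_id!r} unusable — {details}")


@dataclass(frozen=True)
class WindowConfig:
    """Windowing policy for the averaged variance.

    ``window_size`` R defaults to 30 frames (1 s at 30 Hz): short enough to
    resolve within-second fidgeting, long enough to leave 240 windows per
    4-minute recording for a stable average.  Invalid (missing-joint)
    frames are handled by ``invalid_policy``:

    * ``"shrink"`` (default) — a window keeps its valid frames only, with
      the variance denominator reduced to (#valid - 1); windows with fewer
      than 2 valid frames are skipped and do not enter the average;
    * ``"drop_window"`` — any window containing an invalid frame is
      skipped entirely.
    """

    window_size: int = 30
    invalid_policy: str = "shrink"

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2 (sample variance needs R-1 >= 1)")
        if self.invalid_policy not in ("shrink", "drop_window"):
            raise ValueError(f"unknown invalid_policy {self.invalid_policy!r}")


def windowed_average_variance(
    values: np.ndarray,
    valid: np.ndarray | None = None,
    config: WindowConfig = WindowConfig(),
) -> float:
    """Average of within-window sample variances of one parameter series."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    T = values.size
    R = config.window_size
    if T < R:
        raise UnusableFeatureError(f"series length {T} is shorter than the window ({R})")
    if valid is None:
        valid = np.ones(T, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != values.shape:
            raise ValueError("valid mask must match values' shape")

    K = T // R
    v = values[: K * R].reshape(K, R)
    m = valid[: K * R].reshape(K, R)
    counts = m.sum(axis=1)
    if config.invalid_policy == "drop_window":
        keep = counts == R
    else:
        keep = counts >= 2
    if not keep.any():
        raise UnusableFeatureError("no window retains enough valid frames")

    v = np.where(m, v, 0.0)
    mk = m[keep]
    vk = v[keep]
    counts_k = counts[keep].astype(float)
    means = vk.sum(axis=1) / counts_k
    dev = np.where(mk, vk - means[:, None], 0.0)
    variances = (dev**2).sum(axis=1) / (counts_k - 1.0)
    # a window of identical valid values is exactly motionless: force the
    # two-pass cancellation residue to a true zero
    vmax = np.where(mk, vk, -np.inf).max(axis=1)
    vmin = np.where(mk, vk, np.inf).min(axis=1)
    variances[vmax == vmin] = 0.0
    return float(variances.mean())


@dataclass
class FeatureVector:
    """The 11 averaged-variance descriptors of one subject."""

    subject_id: str
    label: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_label(self.label)
        if set(self.values) != set(DESCRIPTORS):
            raise ValueError("a feature vector needs all 11 descriptors")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[d] for d in DESCRIPTORS])


def extract_feature_vector(
    pset: ParameterSeriesSet, config: WindowConfig = WindowConfig()
) -> FeatureVector:
    """Compute all 11 descriptors for one subject.

    Raises :class:`UnusableSubjectError` (with per-descriptor reasons) if
    any descriptor cannot be computed, so that the cohort matrix never
    carries missing cells.
    """
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for name, descriptor in zip(PARAMETERS, DESCRIPTORS):
        series, valid = pset.series(name)
        try:
            values[descriptor] = windowed_average_variance(series, valid, config)
        except UnusableFeatureError as exc:
            reasons[descriptor] = str(exc)
    if reasons:
        raise UnusableSubjectError(pset.subject_id, reasons)
    return FeatureVector(pset.subject_id, pset.label, values)


def build_dataset(cohort: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the cohort dataset matrix.

    Rows are subjects (index = subject_id, original order preserved);
    columns are the 11 descriptors plus the label.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ids = [fv.subject_id for fv in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    df = pd.DataFrame(
        [{**fv.values, LABEL_COLUMN: fv.label} for fv in cohort],
        index=pd.Index(ids, name="subject_id"),
    )
    return df[list(DESCRIPTORS) + [LABEL_COLUMN]]
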