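"""Synthetic two-group cohorts for exercising the pipeline without videos.

Clinical recordings of this kind cannot be shared, so the package ships a
fully seeded generator at two fidelity tiers:

* **Skeleton level** (:func:`generate_cohort`) — a stylised seated child
  in a 1280x720 frame.  Each subject's six bones are animated in *bone
  space*: every bone gets a base direction and length from a fixed seated
  posture, white Gaussian noise on its direction (degrees) and length
  (pixels), and intermittent "fidget events" — raised-cosine rotation
  bursts of the lower body about the mid-hip with partial trunk and
  shoulder follow-through, emulating body spin on a swivel chair, the
  dominant movement of hyperactive children in a consulting room.  Joints
  are then placed hierarchically (mid-hip -> trunk -> neck -> shoulders,
  mid-hip -> hips -> knee) plus global per-joint jitter, dropout and an
  optional second person when exporting pose JSON.  Because the white
  noise acts directly on the 11 skeleton parameters, a noise SD of
  sqrt(v) yields an expected averaged-variance descriptor close to v;
  the per-group defaults are derived this way from published clinical
  reference statistics for a 48+48 outpatient cohort, so group contrasts
  downstream approximate the clinical ones in shape (angle folding and
  event bursts make the match approximate, not exact).

* **Feature level** (:func:`generate_feature_table`) — descriptors drawn
  per subject from truncated-at-zero Gaussians with exact control of each
  group's mean/SD (defaults: the same reference statistics).  Descriptors
  are independent by default — the true between-descriptor correlation is
  not recoverable from published marginals — with an optional
  common-factor correlation knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .features import DESCRIPTORS, LABEL_COLUMN
from .kinematics import ANGLE_PARAMETERS, BONES, LENGTH_PARAMETERS
from .pose_io import write_openpose_json
from .skeleton import ADHD, NON_ADHD, N_JOINTS, SkeletonSequence

__all__ = [
    "GroupStats",
    "REFERENCE_DESCRIPTOR_STATS",
    "MovementModel",
    "CohortConfig",
    "FeatureTableConfig",
    "generate_sequence",
    "generate_cohort",
    "generate_feature_table",
    "export_openpose",
    "expected_auc_gaussian",
    "BASE_POSE",
]


class GroupStats(NamedTuple):
    adhd_mean: float
    adhd_sd: float
    non_adhd_mean: float
    non_adhd_sd: float


#: Published clinical reference statistics (mean, SD per group) of the 11
#: averaged-variance descriptors for a 48+48 ADHD / non-ADHD outpatient
#: cohort; lengths in pixels^2, angles in degrees^2.
REFERENCE_DESCRIPTOR_STATS: dict[str, GroupStats] = {
    "var_l_1_2": GroupStats(39.78, 7.22, 9.77, 1.66),    # right shoulder length
    "var_l_1_5": GroupStats(39.69, 7.11, 10.15, 1.70),   # left shoulder length
    "var_l_8_9": GroupStats(18.29, 3.13, 5.93, 1.09),    # right hip length
    "var_l_8_12": GroupStats(16.72, 2.91, 5.49, 1.14),   # left hip length
    "var_l_9_10": GroupStats(164.99, 41.86, 22.51, 7.31),  # thigh length
    "var_th_1_2": GroupStats(141.33, 19.57, 73.57, 21.37),  # right shoulder angle
    "var_th_1_5": GroupStats(123.39, 17.35, 74.36, 21.33),  # left shoulder angle
    "var_th_8_9": GroupStats(127.43, 18.27, 75.74, 19.27),  # right hip angle
    "var_th_8_12": GroupStats(99.21, 14.22, 51.62, 12.00),  # left hip angle
    "var_th_9_10": GroupStats(157.89, 32.81, 15.37, 6.62),  # thigh angle
    "var_th_8_1": GroupStats(50.60, 17.65, 8.60, 2.53),  # trunk angle
}

# ---------------------------------------------------------------------------
# skeleton-level generator

#: Stylised seated posture (BODY_25 order, pixels in a 1280x720 frame).
#: Shoulders droop and the thigh tilts sideways so that direction noise
#: stays clear of the angle-folding boundaries of the parameter formulas.
BASE_POSE = np.array(
    [
        [640.0, 200.0],  # 0 nose
        [640.0, 260.0],  # 1 neck
        [580.0, 283.0],  # 2 right shoulder
        [558.0, 350.0],  # 3 right elbow
        [552.0, 408.0],  # 4 right wrist
        [700.0, 283.0],  # 5 left shoulder
        [722.0, 350.0],  # 6 left elbow
        [728.0, 408.0],  # 7 left wrist
        [640.0, 430.0],  # 8 mid hip
        [600.0, 450.0],  # 9 right hip
        [560.0, 530.0],  # 10 right knee
        [555.0, 640.0],  # 11 right ankle
        [680.0, 450.0],  # 12 left hip
        [720.0, 530.0],  # 13 left knee
        [725.0, 640.0],  # 14 left ankle
        [625.0, 190.0],  # 15 right eye
        [655.0, 190.0],  # 16 left eye
        [610.0, 200.0],  # 17 right ear
        [670.0, 200.0],  # 18 left ear
        [730.0, 690.0],  # 19 left big toe
        [740.0, 688.0],  # 20 left small toe
        [718.0, 665.0],  # 21 left heel
        [550.0, 690.0],  # 22 right big toe
        [540.0, 688.0],  # 23 right small toe
        [562.0, 665.0],  # 24 right heel
    ]
)

#: Joints placed rigidly relative to an animated anchor joint.
_ANCHORED_JOINTS = {
    0: 1, 15: 1, 16: 1, 17: 1, 18: 1,   # head follows the neck
    3: 2, 4: 2,                          # right arm follows its shoulder
    6: 5, 7: 5,                          # left arm follows its shoulder
    11: 10, 22: 10, 23: 10, 24: 10,      # right foot follows the knee
    13: 12, 14: 12, 19: 12, 20: 12, 21: 12,  # left leg follows the hip
}

#: How strongly each bone's direction follows a swivel (fidget) event.
_EVENT_COUPLING = {
    "right_shoulder": 0.3,
    "left_shoulder": 0.3,
    "right_hip": 0.5,
    "left_hip": 0.5,
    "right_thigh": 1.0,
    "trunk": 0.4,
}

_BONE_ANGLE_PARAM = {
    "right_shoulder": "th_1_2",
    "left_shoulder": "th_1_5",
    "right_hip": "th_8_9",
    "left_hip": "th_8_12",
    "right_thigh": "th_9_10",
    "trunk": "th_8_1",
}
_BONE_LENGTH_PARAM = {
    "right_shoulder": "l_1_2",
    "left_shoulder": "l_1_5",
    "right_hip": "l_8_9",
    "left_hip": "l_8_12",
    "right_thigh": "l_9_10",
}


@dataclass(frozen=True)
class MovementModel:
    """Per-group movement intensity.

    ``angle_noise_sd`` (degrees) and ``length_noise_sd`` (pixels) are
    white-noise SDs per skeleton parameter; ``joint_jitter_sd`` is
    isotropic pixel jitter added to every joint (detector noise);
    fidget events are Poisson-arriving raised-cosine swivel bursts.
    """

    angle_noise_sd: Mapping[str, float]
    length_noise_sd: Mapping[str, float]
    joint_jitter_sd: float = 0.5
    event_rate_per_min: float = 1.0
    event_amplitude_deg: float = 10.0
    event_duration_s: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if set(self.angle_noise_sd) != set(ANGLE_PARAMETERS):
            raise ValueError("angle_noise_sd must cover all 6 angle parameters")
        if set(self.length_noise_sd) != set(LENGTH_PARAMETERS):
            raise ValueError("length_noise_sd must cover all 5 length parameters")

    @classmethod
    def from_descriptor_means(
        cls,
        descriptor_means: Mapping[str, float],
        **kwargs,
    ) -> "MovementModel":
        """Noise SDs set to sqrt(target descriptor): for white noise the
        expected within-window variance equals the noise variance."""
        angle = {p: float(np.sqrt(descriptor_means[f"var_{p}"])) for p in ANGLE_PARAMETERS}
        length = {p: float(np.sqrt(descriptor_means[f"var_{p}"])) for p in LENGTH_PARAMETERS}
        return cls(angle_noise_sd=angle, length_noise_sd=length, **kwargs)

    def scaled(self, factor: float) -> "MovementModel":
        """Scale every noise SD and the event amplitude by ``factor``."""
        return replace(
            self,
            angle_noise_sd={k: v * factor for k, v in self.angle_noise_sd.items()},
            length_noise_sd={k: v * factor for k, v in self.length_noise_sd.items()},
            joint_jitter_sd=self.joint_jitter_sd * factor,
            event_amplitude_deg=self.event_amplitude_deg * factor,
        )


def _default_adhd_model() -> MovementModel:
    means = {d: s.adhd_mean for d, s in REFERENCE_DESCRIPTOR_STATS.items()}
    return MovementModel.from_descriptor_means(
        means,
        joint_jitter_sd=1.0,
        event_rate_per_min=4.0,
        event_amplitude_deg=18.0,
        event_duration_s=(0.5, 2.5),
    )


def _default_control_model() -> MovementModel:
    means = {d: s.non_adhd_mean for d, s in REFERENCE_DESCRIPTOR_STATS.items()}
    return MovementModel.from_descriptor_means(
        means,
        joint_jitter_sd=0.4,
        event_rate_per_min=0.3,
        event_amplitude_deg=5.0,
        event_duration_s=(0.5, 1.5),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study design of a synthetic skeleton-level cohort.

    Defaults mirror the emulated clinical recordings: 48 subjects per
    group, 30 Hz, 4-minute recordings, 1280x720 frames, with the ADHD
    movement model at least as intense as the control model.
    """

    n_per_group: int = 48
    frame_rate: float = 30.0
    duration_s: float = 240.0
    frame_size: tuple[int, int] = (1280, 720)
    adhd_model: MovementModel = field(default_factory=_default_adhd_model)
    control_model: MovementModel = field(default_factory=_default_control_model)
    missing_prob: float = 0.005
    second_person_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("invalid cohort dimensions")
        if not (0 <= self.missing_prob <= 1 and 0 <= self.second_person_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


def _event_envelope(
    model: MovementModel, T: int, frame_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Summed raised-cosine swivel bursts, in degrees, length T."""
    env = np.zeros(T)
    duration_s = T / frame_rate
    n_events = rng.poisson(model.event_rate_per_min * duration_s / 60.0)
    for _ in range(n_events):
        dur = rng.uniform(*model.event_duration_s)
        start = rng.uniform(0.0, max(duration_s - dur, 0.0))
        sign = rng.choice((-1.0, 1.0))
        a = int(start * frame_rate)
        b = min(int((start + dur) * frame_rate), T)
        if b <= a:
            continue
        phase = np.linspace(0.0, 2.0 * np.pi, b - a)
        env[a:b] += sign * model.event_amplitude_deg * 0.5 * (1.0 - np.cos(phase))
    return env


def generate_sequence(
    subject_id: str,
    label: str,
    model: MovementModel,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SkeletonSequence:
    """Synthesise one subject's skeleton sequence."""
    T = int(round(config.duration_s * config.frame_rate))
    base = BASE_POSE

    # base geometry of the six bones
    geo = {}
    for bone in BONES:
        d = base[bone.to_joint] - base[bone.from_joint]
        geo[bone.name] = (float(np.hypot(*d)), float(np.degrees(np.arctan2(d[1], d[0]))))

    env = _event_envelope(model, T, config.frame_rate, rng)

    # per-bone direction (signed, degrees) and length series
    direction = {}
    length = {}
    for bone in BONES:
        L0, psi0 = geo[bone.name]
        sd_a = model.angle_noise_sd[_BONE_ANGLE_PARAM[bone.name]]
        direction[bone.name] = (
            psi0 + _EVENT_COUPLING[bone.name] * env + rng.normal(0.0, sd_a, T)
        )
        if bone.name in _BONE_LENGTH_PARAM:
            sd_l = model.length_noise_sd[_BONE_LENGTH_PARAM[bone.name]]
            length[bone.name] = np.maximum(L0 + rng.normal(0.0, sd_l, T), 1.0)
        else:
            length[bone.name] = np.full(T, L0)

    def unit(name: str) -> np.ndarray:
        rad = np.radians(direction[name])
        return np.column_stack([np.cos(rad), np.sin(rad)])

    xy = np.zeros((T, N_JOINTS, 2))
    xy[:, 8] = base[8]
    # trunk runs neck(1) -> mid-hip(8): the neck sits one trunk length
    # back along the trunk direction from the mid-hip
    xy[:, 1] = xy[:, 8] - length["trunk"][:, None] * unit("trunk")
    xy[:, 2] = xy[:, 1] + length["right_shoulder"][:, None] * unit("right_shoulder")
    xy[:, 5] = xy[:, 1] + length["left_shoulder"][:, None] * unit("left_shoulder")
    xy[:, 9] = xy[:, 8] + length["right_hip"][:, None] * unit("right_hip")
    xy[:, 12] = xy[:, 8] + length["left_hip"][:, None] * unit("left_hip")
    xy[:, 10] = xy[:, 9] + length["right_thigh"][:, None] * unit("right_thigh")
    for j, anchor in _ANCHORED_JOINTS.items():
        xy[:, j] = xy[:, anchor] + (base[j] - base[anchor])

    if model.joint_jitter_sd > 0:
        xy += rng.normal(0.0, model.joint_jitter_sd, xy.shape)
    nx, ny = config.frame_size
    xy[:, :, 0] = np.clip(xy[:, :, 0], 0, nx - 1)
    xy[:, :, 1] = np.clip(xy[:, :, 1], 0, ny - 1)

    conf = rng.uniform(0.5, 0.95, (T, N_JOINTS))
    missing = rng.random((T, N_JOINTS)) < config.missing_prob
    conf[missing] = 0.0
    xy[missing] = 0.0

    return SkeletonSequence(
        subject_id=subject_id,
        label=label,
        xy=xy,
        confidence=conf,
        frame_size=config.frame_size,
        frame_rate=config.frame_rate,
    )


def generate_cohort(
    config: CohortConfig = CohortConfig(), seed: int | None = None
) -> list[SkeletonSequence]:
    """Generate the full two-group cohort (ADHD subjects first).

    Each subject gets an independent child stream of the master seed, so
    the cohort is bit-reproducible and any subject regenerates alone.
    """
    children = np.random.SeedSequence(seed).spawn(2 * config.n_per_group)
    cohort = []
    for i in range(config.n_per_group):
        rng = np.random.default_rng(children[i])
        cohort.append(
            generate_sequence(f"adhd_{i + 1:03d}", ADHD, config.adhd_model, config, rng)
        )
    for i in range(config.n_per_group):
        rng = np.random.default_rng(children[config.n_per_group + i])
        cohort.append(
            generate_sequence(
                f"ctrl_{i + 1:03d}", NON_ADHD, config.control_model, config, rng
            )
        )
    return cohort


def export_openpose(
    seq: SkeletonSequence,
    directory: str | Path,
    config: CohortConfig = CohortConfig(),
    seed: int | None = None,
) -> None:
    """Write a sequence as pose-estimator JSON files, with nuisance people.

    With probability ``config.second_person_prob`` per frame a second,
    smaller skeleton (a parent or clinician at the frame edge) is written
    after the subject, exercising primary-person selection on read.
    """
    rng = np.random.default_rng(seed)
    extra: dict[int, list[np.ndarray]] = {}
    nx, _ = config.frame_size
    for t in range(seq.n_frames):
        if rng.random() < config.second_person_prob:
            pose = BASE_POSE * 0.85 + np.array([0.35 * nx, 40.0])
            pose = pose + rng.normal(0.0, 2.0, pose.shape)
            person = np.column_stack([pose, rng.uniform(0.3, 0.7, N_JOINTS)])
            extra[t] = [person]
    write_openpose_json(seq, directory, extra_people=extra)


# ---------------------------------------------------------------------------
# feature-level generator

@dataclass(frozen=True)
class FeatureTableConfig:
    """Exact distributional control of a descriptor table.

    Each descriptor is drawn from a Gaussian with its group's mean/SD,
    truncated at zero (descriptors are variances).  ``correlation`` adds
    an equicorrelated common factor across descriptors before truncation
    (0 = independent, the default).
    """

    group_stats: Mapping[str, GroupStats] = field(
        default_factory=lambda: dict(REFERENCE_DESCRIPTOR_STATS)
    )
    n_per_group: int = 48
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if set(self.group_stats) != set(DESCRIPTORS):
            raise ValueError("group_stats must cover all 11 descriptors")
        for d, s in self.group_stats.items():
            if s.adhd_sd <= 0 or s.non_adhd_sd <= 0:
                raise ValueError(f"{d}: SDs must be positive")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")


def _draw_group(
    config: FeatureTableConfig,
    means: np.ndarray,
    sds: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    rho = config.correlation
    common = rng.normal(size=(n, 1))
    z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.normal(size=(n, len(means)))
    x = means + sds * z
    # truncate at zero by redrawing the idiosyncratic part of offending cells
    for _ in range(1000):
        rows, cols = np.nonzero(x < 0)
        if rows.size == 0:
            return x
        z_new = np.sqrt(rho) * common[rows, 0] + np.sqrt(1.0 - rho) * rng.normal(
            size=rows.size
        )
        x[rows, cols] = means[cols] + sds[cols] * z_new
    raise RuntimeError("truncation failed to converge; check means/SDs")


def generate_feature_table(
    config: FeatureTableConfig = FeatureTableConfig(), seed: int | None = None
) -> pd.DataFrame:
    """Draw a cohort dataset matrix directly at the descriptor level."""
    rng = np.random.default_rng(seed)
    means_a = np.array([config.group_stats[d].adhd_mean for d in DESCRIPTORS])
    sds_a = np.array([config.group_stats[d].adhd_sd for d in DESCRIPTORS])
    means_c = np.array([config.group_stats[d].non_adhd_mean for d in DESCRIPTORS])
    sds_c = np.array([config.group_stats[d].non_adhd_sd for d in DESCRIPTORS])
    n = config.n_per_group
    block_a = _draw_group(config, means_a, sds_a, n, rng)
    block_c = _draw_group(config, means_c, sds_c, n, rng)
    ids = [f"adhd_{i + 1:03d}" for i in range(n)] + [f"ctrl_{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(
        np.vstack([block_a, block_c]),
        columns=list(DESCRIPTORS),
        index=pd.Index(ids, name="subject_id"),
    )
    df[LABEL_COLUMN] = [ADHD] * n + [NON_ADHD] * n
    return df


def expected_auc_gaussian(mu1: float, sd1: float, mu0: float, sd0: float) -> float:
    """Closed-form AUC of two independent Gaussian classes.

    AUC = Phi((mu1 - mu0) / sqrt(sd1^2 + sd0^2)); the analytic oracle used
    to predict cutoff/classification results on generated tables.
    """
    return float(norm.cdf((mu1 - mu0) / np.hypot(sd1, sd0)))


# ---------------------------------------------------------------------------
# flat config files

def feature_table_config_from_yaml(path: str | Path) -> FeatureTableConfig:
    """Load a flat key/value YAML override of the feature-table defaults.

    Recognised keys: ``n_per_group``, ``correlation``, and per-descriptor
    ``<descriptor>.<field>`` entries such as
    ``var_th_9_10.adhd_mean: 120``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    stats = {d: s for d, s in REFERENCE_DESCRIPTOR_STATS.items()}
    simple = {}
    for key, value in raw.items():
        if "." in str(key):
            descriptor, fld = key.split(".", 1)
            stats[descriptor] = stats[descriptor]._replace(**{fld: float(value)})
        else:
            simple[key] = value
    return FeatureTableConfig(
        group_stats=stats,
        n_per_group=int(simple.get("n_per_group", 48)),
        correlation=float(simple.get("correlation", 0.0)),
    )


def cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    """Load a flat key/value YAML override of the cohort defaults.

    Recognised keys: ``n_per_group``, ``frame_rate``, ``duration_s``,
    ``missing_prob``, ``second_person_prob``, and per-group movement
    scale factors ``adhd_scale`` / ``control_scale`` applied to the
    default movement models.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    adhd_model = _default_adhd_model().scaled(float(raw.pop("adhd_scale", 1.0)))
    control_model = _default_control_model().scaled(float(raw.pop("control_scale", 1.0)))
    allowed = {"n_per_group", "frame_rate", "duration_s", "missing_prob", "second_person_prob"}
    if unknown := set(raw) - allowed:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(adhd_model=adhd_model, control_model=control_model, **raw)
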