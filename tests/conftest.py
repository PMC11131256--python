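import numpy as np
import pytest

from skelquant.skeleton import ADHD, NON_ADHD, N_JOINTS, SkeletonSequence
from skelquant.synthetic import FeatureTableConfig, generate_feature_table


def random_sequence(
    rng: np.random.Generator,
    n_frames: int = 12,
    missing_prob: float = 0.1,
    label: str = NON_ADHD,
    subject_id: str = "s1",
) -> SkeletonSequence:
    """A structurally valid random sequence with some missing joints."""
    xy = rng.uniform(1, 700, size=(n_frames, N_JOINTS, 2))
    conf = rng.uniform(0.2, 1.0, size=(n_frames, N_JOINTS))
    missing = rng.random((n_frames, N_JOINTS)) < missing_prob
    conf[missing] = 0.0
    xy[missing] = 0.0
    return SkeletonSequence(
        subject_id=subject_id, label=label, xy=xy, confidence=conf, frame_size=(720, 720)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def reference_table():
    """96-subject feature table drawn at the clinical reference statistics."""
    return generate_feature_table(FeatureTableConfig(), seed=11)
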