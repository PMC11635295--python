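import numpy as np
import pytest

from nirsdoc.connectivity import FCMatrix
from nirsdoc.montage import default_montage
from nirsdoc.optics import default_optics
from nirsdoc.synthcohort import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def optics():
    return default_optics()


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort with all three planted defects (session-cached)."""
    cfg = SynthConfig(n_group_a=2, n_group_b=2, duration=330.0, seed=11)
    recordings, gt = generate_cohort(cfg)
    return cfg, recordings, gt


def fc_from_matrix(r: np.ndarray, subject_id: str = "toy") -> FCMatrix:
    r = np.asarray(r, dtype=float)
    return FCMatrix(r=r, active=np.ones(len(r), dtype=bool), subject_id=subject_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
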