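import numpy as np
import pytest

from limbrsa.config import StudyConfig
from limbrsa.synthetic import make_canonical_rdm


@pytest.fixture
def canonical():
    return make_canonical_rdm()


@pytest.fixture
def small_config():
    """Lightweight study configuration for fast unit tests."""
    return StudyConfig(
        n_per_group={"amputee": 4, "congenital": 3, "control": 3},
        n_voxels_per_roi={"SI_contra": 40, "M1_contra": 40, "SI_ipsi": 40, "V5": 30},
        n_residual_timepoints=80,
        residual_dof=70,
        rng_seed=123,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
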