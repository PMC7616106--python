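import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from cpfe_progression.config import CohortConfig
from cpfe_progression.simulate import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-subject cohort shared by read-only tests."""
    cfg = CohortConfig(n_subjects=150, seed=20240901)
    patients, pft, truth = generate_cohort(cfg)
    return cfg, patients, pft, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
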