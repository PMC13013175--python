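import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from rivapk import study
from rivapk.cohort import generate_cohort, generate_dataset
from rivapk.pkmodel import IndivParams


@pytest.fixture(scope="session")
def typical_params() -> IndivParams:
    """Typical-subject parameters of the reference final model."""
    return study.final_model().typical_params()


@pytest.fixture(scope="session")
def final_model():
    return study.final_model()


@pytest.fixture(scope="session")
def study_dataset():
    """One synthetic replicate of the sparse 38-subject study design."""
    cfg = study.study_design(seed=20240)
    cohort = generate_cohort(cfg)
    return generate_dataset(cohort, study.final_model(), cfg, seed=20241)


def random_params(rng: np.random.Generator, spread: float = 0.5) -> IndivParams:
    """Log-normal jitter around the typical values, for property tests."""
    m = study.final_model()
    vals = np.array(m.theta) * np.exp(rng.normal(0.0, spread, size=5))
    return IndivParams(*vals)
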