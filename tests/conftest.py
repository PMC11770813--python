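import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from deutg import CorrectionOptions, IonFormula, build_correction_matrix


@pytest.fixture(scope="session")
def default_matrix() -> np.ndarray:
    """Natural-abundance/purity correction matrix for C6H11O6, K=2."""
    return build_correction_matrix(IonFormula(), CorrectionOptions())


@pytest.fixture(scope="session")
def pure_matrix() -> np.ndarray:
    """Same matrix at tracer purity 1 (no impurity channel)."""
    return build_correction_matrix(IonFormula(), CorrectionOptions(tracer_purity=1.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
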