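import numpy as np
import pytest

from betakin.cascade import CascadeParams
from betakin.condensation import CondensationScheme
from betakin.kinetics import KineticParams

# generating truths used across the suite (values as printed in the source study)
PAPER_KM = 1.36  # mM
PAPER_VMAX = 5.26  # uM/min
PAPER_KCAT = 0.50  # 1/min
PAPER_K_COND = 189.0  # 1/h/M
PAPER_DOPA_M = 3.5e-3  # M


@pytest.fixture
def mm_truth() -> KineticParams:
    return KineticParams(Km=PAPER_KM, Vmax=PAPER_VMAX)


@pytest.fixture
def cond_truth() -> CondensationScheme:
    return CondensationScheme(k=PAPER_K_COND, DOPA_conc=PAPER_DOPA_M)


@pytest.fixture
def demo_cascade() -> CascadeParams:
    return CascadeParams()


@pytest.fixture
def time_grid() -> np.ndarray:
    return np.linspace(0.0, 40.0, 201)
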