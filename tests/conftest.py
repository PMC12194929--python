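import numpy as np
import pytest

from regcircuit.motif import MarkovBackground


@pytest.fixture
def uniform_bg() -> MarkovBackground:
    return MarkovBackground.uniform(0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_pwm(rng: np.random.Generator, width: int, motif_id: str = "rand"):
    """Strictly positive random PWM with a dense score spectrum."""
    from regcircuit.motif import PWM

    mat = rng.dirichlet(np.full(4, 1.0), size=width)
    mat = (mat + 0.01) / (1 + 0.04)
    return PWM(motif_id=motif_id, matrix=mat, nsites=20)
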