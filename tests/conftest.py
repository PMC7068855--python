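import numpy as np
import pytest

from pwmgemm import PWM, BackgroundModel


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture
def toy_pwm_m1():
    """Single-column PWM with weights (A,C,G,T) = (1, -1, -1, 0)."""
    return PWM(name="toy1", weights=np.array([[1.0], [-1.0], [-1.0], [0.0]]))


@pytest.fixture
def toy_pwm_m2():
    """Two columns, each (1, -1, -1, 0)."""
    return PWM(name="toy2", weights=np.array([[1.0, 1.0], [-1.0, -1.0], [-1.0, -1.0], [0.0, 0.0]]))
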