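import numpy as np
import pytest

from snbda import Window, PointPattern, generate_study


@pytest.fixture(scope="session")
def clustered_study():
    """One deterministic clustered study system (~26 nests, 10 diffusions)."""
    return generate_study(kind="clustered", seed=42)


@pytest.fixture(scope="session")
def csr_study():
    """CSR control: random pattern, purely asocial diffusions."""
    return generate_study(kind="csr", seed=42)


@pytest.fixture
def square_pattern():
    """Four points on a small square, radius 0.3, in a generous window."""
    coords = np.array([[0.3, 0.3], [0.7, 0.3], [0.3, 0.7], [0.7, 0.7]])
    return PointPattern(["a", "b", "c", "d"], coords, 0.3, Window(0, 1, 0, 1))
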