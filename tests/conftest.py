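import numpy as np
import pytest

from smchain import CellPattern, DecisionProfile


@pytest.fixture
def lld() -> CellPattern:
    """The canonical two-light-one-dark repeating pattern (alpha = 2/3)."""
    return CellPattern.from_string("LLD")


@pytest.fixture
def walker() -> DecisionProfile:
    """The worked-example walker: strong deliberation, cautious primary emotions."""
    return DecisionProfile(p_r=0.8, p_e1=0.1)


def lazy_power_iteration(transition: np.ndarray, max_steps: int = 1_000_000) -> np.ndarray:
    """Independent stationary-distribution oracle.

    Iterates the lazy chain (I + T) / 2, which shares its stationary
    vector with T but is aperiodic for every ring size (a plain +/-1 walk
    on an even ring is 2-periodic, so iterating T itself need not
    converge).  Runs to numerical fixation or ``max_steps``.
    """
    n = transition.shape[0]
    lazy = 0.5 * (np.eye(n) + transition)
    pi = np.full(n, 1.0 / n)
    for _ in range(max_steps):
        new = pi @ lazy
        if np.abs(new - pi).max() < 1e-16:
            return new
        pi = new
    return pi
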