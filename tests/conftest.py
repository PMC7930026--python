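"""Shared fixtures: random well-posed network systems and data."""

import numpy as np
import pytest

from ddnetctrl import LinearNetworkSystem, select_io_nodes


def make_random_system(n: int, m: int, p: int, T: int, seed: int,
                       sigma_min: float = 1e-3,
                       scale: float | None = None) -> LinearNetworkSystem:
    """Dense Gaussian network with random i/o node selection, resampled
    until the output controllability matrix is well conditioned."""
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(n) if scale is None else scale
    for _ in range(50):
        A = rng.standard_normal((n, n)) * scale
        try:
            B, C = select_io_nodes(A, m, p, T,
                                   seed=int(rng.integers(2**31)),
                                   sigma_min=sigma_min, max_tries=200)
            return LinearNetworkSystem(A, B, C)
        except RuntimeError:
            continue
    raise RuntimeError("could not build a well-posed random system")


@pytest.fixture
def random_system():
    return make_random_system
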