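import numpy as np
import pytest

from nkcollective import NKLandscape, generate_landscape


@pytest.fixture(scope="session")
def smooth_landscape() -> NKLandscape:
    """N=10, K=1: few local optima, solvable by hill climbing."""
    return generate_landscape(10, 1, 42)


@pytest.fixture(scope="session")
def rugged_landscape() -> NKLandscape:
    """N=10, K=8: many local optima."""
    return generate_landscape(10, 8, 7)


@pytest.fixture(scope="session")
def additive_landscape() -> NKLandscape:
    """N=10, K=0: single-peaked, every improving flip is independent."""
    return generate_landscape(10, 0, 99)


@pytest.fixture()
def handbuilt_2d() -> NKLandscape:
    """Hand-built N=2, K=0 landscape with known contribution tables.

    dim 0 contributes 0.2 (bit=0) or 0.4 (bit=1); dim 1 contributes 0.6 or 0.8.
    Raw payoffs: (0,0)=0.4, (1,0)=0.5, (0,1)=0.5, (1,1)=0.6; max raw = 0.6.
    """
    return NKLandscape(
        N=2, K=0,
        interaction_map=np.empty((2, 0), dtype=int),
        contribution_tables=np.array([[0.2, 0.4], [0.6, 0.8]]),
    )


@pytest.fixture()
def flat_2d() -> NKLandscape:
    """N=2, K=0 landscape where every solution pays the same (tie handling)."""
    return NKLandscape(
        N=2, K=0,
        interaction_map=np.empty((2, 0), dtype=int),
        contribution_tables=np.array([[0.5, 0.5], [0.5, 0.5]]),
    )
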