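import numpy as np
import pytest

from swarmalators import ModelParams, SwarmState, assign_chirality


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(rng, n=7, chiral=False, mixed_signs=True, spread=True, scale=2.0, t=0.0):
    """Random but well-separated state for oracle comparisons."""
    omega = rng.uniform(1.0, 3.0, n) if spread else np.ones(n)
    if mixed_signs:
        omega = omega * rng.choice([-1.0, 1.0], size=n)
    c, radii = assign_chirality(omega, 1.0 if chiral else 0.0)
    return SwarmState(
        pos=rng.uniform(-scale, scale, (n, 2)),
        phase=rng.uniform(-np.pi, np.pi, n),
        omega=omega,
        c=c,
        R=radii,
        t=t,
    )


PARAM_GRID = [
    ModelParams(J=0.7, K=1.2),
    ModelParams(J=-0.4, K=-0.6, sigma=2.0),
    ModelParams(J=1.0, K=1.0, freq_coupling=True),
    ModelParams(J=0.9, K=0.5, sigma=1.5, freq_coupling=True),
    ModelParams(J=0.5, K=0.8, variant="embryonic", alpha=0.7),
]


@pytest.fixture(params=PARAM_GRID, ids=["global", "local", "freq", "freq_local", "embryonic"])
def any_params(request):
    return request.param
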