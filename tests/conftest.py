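import numpy as np
import pytest

from lymphpump.params import load_config
from lymphpump.transport import build_grid


@pytest.fixture
def defaults():
    """Fresh default parameter bundle (mutable per test)."""
    return load_config()


@pytest.fixture
def grid(defaults):
    return build_grid(defaults.run, defaults.phasic.h)


@pytest.fixture
def uniform_grid_factory(defaults):
    """Uniform grids (no refinement) for convergence studies."""
    def make(n_per_h: int, span: float = 3.0):
        p = load_config({"run.n_per_h": n_per_h, "run.refine_factor": 1,
                         "run.span": span})
        return build_grid(p.run, p.phasic.h)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
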