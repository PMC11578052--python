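import numpy as np
import pytest

from bpcea.config import validate_config
from bpcea.model import Model
from bpcea.synthetic import SyntheticSpec, generate_parameter_set


@pytest.fixture(scope="session")
def default_config():
    return validate_config(generate_parameter_set(SyntheticSpec(seed=1)))


@pytest.fixture(scope="session")
def default_model(default_config):
    return Model(default_config)


@pytest.fixture(scope="session")
def default_traces(default_model):
    return default_model.run_all()


def enumerate_path_totals(matrices, utilities, costs, rate, n_cycles, absorbing, start=0):
    """Brute-force expectation over explicit state paths.

    Accrues utility/cost on the post-transition state of each cycle with
    end-of-cycle discounting, mirroring the engine's accounting but via
    exhaustive path recursion rather than matrix propagation.
    """
    n = len(utilities)
    totals = {"qaly": 0.0, "cost": 0.0}

    def rec(state, t, prob):
        if t == n_cycles:
            return
        M = matrices[t]
        dfac = (1.0 + rate) ** (-(t + 1))
        for nxt in range(n):
            p = prob * M[state][nxt]
            if p == 0.0:
                continue
            totals["qaly"] += p * utilities[nxt] * dfac
            totals["cost"] += p * costs[nxt] * dfac
            if nxt not in absorbing:
                rec(nxt, t + 1, p)

    rec(start, 0, 1.0)
    return totals["qaly"], totals["cost"]


def assert_trace_valid(trace, atol=1e-9):
    occ = trace.occupancy
    np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=atol)
    assert (occ >= -atol).all()
    from bpcea.states import STATE_SPACE

    for idx in STATE_SPACE.absorbing_indices:
        col = occ[:, idx]
        assert (np.diff(col) >= -atol).all(), "absorbing occupancy decreased"
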