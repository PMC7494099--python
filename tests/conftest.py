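import numpy as np
import pytest

from leakyclock.param_search import ParameterSet, search_oscillating_sets


def make_symmetric_params(model_id: str, gamma=0.5, gamma_deg=50.0,
                          kappa=50.0, n=4, rho=0.5) -> ParameterSet:
    """A hand-specified, cyclically symmetric parameter set (test helper)."""
    from leakyclock.models import build_model
    spec = build_model(model_id)
    values = {}
    for slot, cls in spec.sampled_slots().items():
        values[slot] = {"gamma": gamma, "gamma_deg": gamma_deg,
                        "kappa": kappa, "n": float(n), "rho": rho}[cls]
    return ParameterSet(model_id, values)


@pytest.fixture(scope="session")
def m1_oscillating_set() -> ParameterSet:
    """One accepted, 24 h-rescaled M1 parameter set (shared across tests)."""
    res = search_oscillating_sets("M1", 1, np.random.default_rng(4242))
    return res.sets[0]
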