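import numpy as np
import pytest

from perisilence import SSAConfig, default_parameters, gillespie_run


@pytest.fixture(scope="session")
def wt():
    """Reference three-variable (wild-type) parameter set."""
    return default_parameters("three")


@pytest.fixture(scope="session")
def wt5():
    """Reference five-variable parameter set."""
    return default_parameters("five")


@pytest.fixture(scope="session")
def warm_ssa(wt):
    """Compile the SSA kernel once per session (tiny throwaway run)."""
    cfg = SSAConfig(t_end=20.0, burn_in=10.0, sample_step=10.0, seed=0)
    gillespie_run(wt, cfg)
    return True


def jittered_parameters(wt, rng, rel=0.2):
    """A random parameter set within +/-rel of the reference rates."""
    d = wt.to_dict()
    for key in ("alpha", "delta1", "delta2", "delta3", "gamma", "epsilon",
                "phi", "zeta"):
        d[key] *= float(rng.uniform(1 - rel, 1 + rel))
    for key in ("k1", "k2", "k3"):
        d[key] = min(1.0, d[key] * float(rng.uniform(1 - rel, 1 + rel)))
    return type(wt).from_dict(d)
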