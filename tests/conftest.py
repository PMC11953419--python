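import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pecircuit as pc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("pecircuit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mfn_params():
    """All three validated circuit variants, built once."""
    return {v: pc.build_mfn(v) for v in ("MFN1", "MFN2", "MFN3")}


@pytest.fixture(scope="session")
def mfn1(mfn_params):
    return mfn_params["MFN1"]


@pytest.fixture(scope="session")
def networks(mfn_params):
    """Hierarchy networks per variant (default lambdas), built once."""
    nets = {}
    for v, params in mfn_params.items():
        g_n, g_p = pc.measure_gains(params)
        nets[v] = pc.HierarchyNetwork(lower=params, higher=params,
                                      g_npe=g_n, g_ppe=g_p)
    return nets


@pytest.fixture(scope="session")
def net_mfn1(networks):
    return networks["MFN1"]


@pytest.fixture(scope="session")
def net_fig2(mfn_params):
    params = mfn_params["MFN1"]
    g_n, g_p = pc.measure_gains(params)
    return pc.HierarchyNetwork(lower=params, higher=params,
                               lambda_low=pc.LAMBDA_LOW_FIG2,
                               g_npe=g_n, g_ppe=g_p)


def spawn_seeds(base: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 for a run family."""
    ss = np.random.SeedSequence(base)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]
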