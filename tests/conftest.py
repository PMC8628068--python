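import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plasmidcost as pc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_table():
    return pc.load_reference_table()


@pytest.fixture
def small_config():
    """2 plasmids x 1 mutation factorial with sampling noise, fixed seed."""
    return pc.SimulationConfig.factorial(
        plasmids={"pA": 0.90, "pB": 0.75},
        mutations={"m1": 0.80},
        seed=42,
    )


@pytest.fixture
def uniform_frequencies():
    """A flat codon frequency table (every codon weight 1)."""
    from itertools import product

    return {"".join(c): 10.0 for c in product("ACGT", repeat=3)}


def make_estimates(ws, level="vs_gfp_reference", plasmid=None, mutation=None):
    return [
        pc.FitnessEstimate(w=w, level=level, plasmid=plasmid, mutation=mutation,
                           replicate=i)
        for i, w in enumerate(ws, 1)
    ]


@pytest.fixture
def estimates_factory():
    return make_estimates


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
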