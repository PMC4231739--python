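import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tetradna import sequence as sq
from tetradna import simulate as sim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset() -> sim.GeneratorSpec:
    return sim.paper2014()


@pytest.fixture(scope="session")
def rr_table(preset):
    """RR-context fragment (central GG step) with coupled BII/H-bond states."""
    return sim.generate_series(preset, "AGGC", 100_000, seed=101)


@pytest.fixture(scope="session")
def cg_table(preset):
    """CG-context fragment with the two twist wells near 20° and 40°."""
    return sim.generate_series(preset, "GCGC", 100_000, seed=202)


@pytest.fixture(scope="session")
def oligomer_table(preset):
    """Full 18-level series for the ACGT repeat design."""
    spec = dataclasses.replace(preset, fields=("inter", "backbone", "wc"))
    design = sq.build_oligomer("ACGT")
    return sim.generate_series(spec, design.sequence, 30_000, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
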