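import numpy as np
import pytest

from tflink import simulate as sim


@pytest.fixture(scope="session")
def default_study():
    """One shared default-scenario simulation (seed fixed)."""
    return sim.simulate_study(sim.SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_genome(rng):
    """A 200 kb single-chromosome genome as a plain string mapping."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=200_000).tobytes().decode("ascii")
    return {"chr1": seq}
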