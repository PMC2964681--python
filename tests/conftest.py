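import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_core():
    from ryhbkit.srna_discovery import default_core_sequence

    return default_core_sequence()


@pytest.fixture(scope="session")
def sim_pair():
    """A default simulated genome pair with planted primer sites (seed 1)."""
    from ryhbkit.genome_model import PrimerPair
    from ryhbkit.synthetic_data import GenomeSimParams, simulate_genome_pair

    primers = PrimerPair("sim-F/R", "TCTGACGTTGTTAAAGTGCTCC", "CCTAATGCGCCTATTCGCT")
    params = GenomeSimParams(seed=1, primer_pair=primers)
    ref, qry, truth = simulate_genome_pair(params)
    return ref, qry, truth, primers


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
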