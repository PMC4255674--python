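import numpy as np
import pytest

from inseqtools.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 60 kb single-replicon experiment with reads, shared across tests."""
    outdir = tmp_path_factory.mktemp("sim") / "bundle"
    config = SimConfig(seed=7, replicon_lengths=(60_000,),
                       gc_fractions=(0.61,), copy_number_factors=(1.0,))
    truth = simulate_experiment(config, outdir)
    return outdir, config, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genome(rng, length, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
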