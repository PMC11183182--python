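import numpy as np
import pytest

from methyreg.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact ground-truthed fixture shared across test modules."""
    outdir = tmp_path_factory.mktemp("fixture_small")
    spec = FixtureSpec(
        seed=7,
        genome_length=30_000,
        n_genes=18,
        n_occurrences=120,
        n_rtmg_genes=3,
    )
    truth = generate_fixture(spec, outdir, background="uniform")
    return spec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genome(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
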