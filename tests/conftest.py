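import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic FASTQ dataset shared by integration tests."""
    from kmerdisk.simulate import SyntheticSpec, generate_reads

    spec = SyntheticSpec(genome_length=20_000, coverage=10, seed=3)
    d = tmp_path_factory.mktemp("reads")
    paths = generate_reads(spec, d)
    return spec, [str(p) for p in paths]


def random_kmer(rng, k):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=k))
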