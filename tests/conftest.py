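import numpy as np
import pytest

import foldscan as fs


@pytest.fixture(scope="session")
def blosum():
    return fs.load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def small_benchmark():
    """A small three-fold world shared by integration-style tests."""
    spec = fs.SyntheticFoldSpec(
        n_folds=3, seeds_per_fold=1, homologs_per_seed=6, queries_per_fold=2, seed=11
    )
    return fs.make_benchmark(spec)


@pytest.fixture(scope="session")
def small_collection(small_benchmark, blosum):
    return small_benchmark.build_collection(blosum)


def random_sequence(rng: np.random.Generator, length: int, seq_id: str = "s"):
    from foldscan.synthetic_fixtures import generate_ancestor

    return generate_ancestor(length, rng, seq_id=seq_id)
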