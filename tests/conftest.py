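import numpy as np
import pytest

from streambeta import OccurrenceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_occurrence(rng, n_sites=15, n_species=19, p=0.4):
    """Random incidence matrix with every site non-empty."""
    while True:
        inc = (rng.random((n_sites, n_species)) < p).astype(np.int8)
        if (inc.sum(axis=1) > 0).all():
            return OccurrenceMatrix(
                tuple(f"s{i}" for i in range(n_sites)),
                tuple(f"sp{j}" for j in range(n_species)),
                inc,
            )
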