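import numpy as np
import pytest

from motudelim import (
    Method,
    Model,
    Partition,
    SimConfig,
    build_matrix,
    simulate_library,
)
from motudelim.distances import DistanceMatrix


@pytest.fixture(scope="session")
def clean_library():
    """5 species x 5 specimens, realized intra <= 1%, inter >= 5%.

    The seed realises the construction premise (all intraspecific distances
    below 1%) that the barcode-gap examples assume.
    """
    return simulate_library(
        SimConfig(n_species=5, specimens_per_species=5, seed=22)
    )


@pytest.fixture(scope="session")
def clean_matrix(clean_library):
    library, _ = clean_library
    return build_matrix(library, Model.K2P)


@pytest.fixture(scope="session")
def truth_partition(clean_library):
    _, truth = clean_library
    ids = {motu: k for k, motu in enumerate(dict.fromkeys(truth.assignment.values()))}
    return Partition(
        Method.TRUTH, {sid: ids[m] for sid, m in truth.assignment.items()}
    )


def truth_to_partition(truth):
    ids = {motu: k for k, motu in enumerate(dict.fromkeys(truth.assignment.values()))}
    return Partition(
        Method.TRUTH, {sid: ids[m] for sid, m in truth.assignment.items()}
    )


def matrix_from_values(ids, values, model=Model.P, sites=600):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(
        ids=list(ids),
        model=model,
        values=v,
        site_counts=np.full_like(v, sites, dtype=int),
        saturated=np.zeros_like(v, dtype=bool),
    )
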