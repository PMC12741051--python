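import numpy as np
import pytest

from ligomap.datatypes import ProteinRecord, SubstitutionMatrix
from ligomap.distances import EMERGENT_COMPONENTS, compute_all_distances
from ligomap.synthetic import SyntheticConfig, generate_ligome

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def blosum_dict(blosum):
    """BLOSUM62 as a plain (a, b) -> score dict for the brute-force oracles."""
    return {
        (a, b): blosum.scores[i, j]
        for i, a in enumerate(blosum.alphabet)
        for j, b in enumerate(blosum.alphabet)
    }


@pytest.fixture(scope="session")
def ligome():
    """Default planted dataset: 3 classes, 6 families, 10 members each."""
    return generate_ligome(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_ligome():
    """30-protein fixture (family size 5) for the exhaustive measure checks."""
    return generate_ligome(SyntheticConfig(seed=2, family_size=5))


@pytest.fixture(scope="session")
def emergent_matrices(ligome):
    ds, _ = ligome
    return list(compute_all_distances(ds, measures=EMERGENT_COMPONENTS).values())


@pytest.fixture(scope="session")
def all_matrices(small_ligome):
    ds, _ = small_ligome
    return compute_all_distances(ds)


def random_protein(rng, length, pid="P"):
    seq = "".join(rng.choice(list(AA), size=length))
    return ProteinRecord(id=pid, sequence=seq)
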