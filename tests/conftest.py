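import numpy as np
import pytest

from tmsrep.pairwise import AMINO_ACIDS, DEFAULT_SCHEME
from tmsrep.synthetic import make_family, scenario_for_preset


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def family_3p3():
    """A 3+3 family at the calibrated ~30% inter-half identity regime."""
    sc = scenario_for_preset("3+3", n=30, d=0.6, seed=2024)
    records, truths, manifest = make_family(sc)
    return records, truths, manifest


@pytest.fixture(scope="session")
def annotations_3p3(family_3p3):
    _, truths, _ = family_3p3
    return {t.id: t.tms_intervals for t in truths}


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
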