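import pytest

from peptilap.model import PrecursorProtein
from peptilap.ortho import OrthoGroup
from peptilap.simulate import SimulationConfig, simulate_dataset


#: small, fast simulator configuration used where many seeds are iterated
SMALL_SIM = dict(
    n_prohormones=5,
    n_background_proteins=5,
    n_samples=3,
    ladder_rate=2.0,
)


@pytest.fixture
def glucagon_like_precursor():
    """A toy precursor embedding a glucagon-style mature peptide between a
    dibasic site (…DKR) and a trailing dibasic context (RRA…)."""
    seq = "MKSIYFVAGLFVMLVQG" + "DKR" + "HSQGTFTSDYSKYLDS" + "RRA" + "QDFVQWLMNT"
    return PrecursorProtein(accession="GCG", sequence=seq, gene="Gcg")


@pytest.fixture
def toy_group(glucagon_like_precursor):
    return OrthoGroup(group_id="g1", members=[glucagon_like_precursor.accession],
                      is_prohormone=True)


@pytest.fixture
def small_dataset():
    return simulate_dataset(SimulationConfig(**SMALL_SIM, seed=7))
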