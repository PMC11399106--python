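import pytest

from rnaswitch.backends import ExactToyBackend, sample_ensemble
from rnaswitch.config import RunConfig
from rnaswitch.conflict import predict_switch
from rnaswitch.core import RnaSequence
from rnaswitch.fixtures import make_bistable_sequence


@pytest.fixture(scope="session")
def backend():
    return ExactToyBackend()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def bistable():
    """Default designed bistable fixture (27 nt, stems of 7 pairs)."""
    return make_bistable_sequence(seed=0)


@pytest.fixture(scope="session")
def bistable_ensemble(bistable, backend):
    return sample_ensemble(bistable.sequence, 1000, seed=7, backend=backend)


@pytest.fixture(scope="session")
def bistable_prediction(bistable, bistable_ensemble, config):
    pair = predict_switch(bistable.sequence, config=config, ensemble=bistable_ensemble)
    assert pair is not None
    return pair


def make_seq(residues: str, id: str = "t") -> RnaSequence:
    return RnaSequence(id=id, residues=residues)
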