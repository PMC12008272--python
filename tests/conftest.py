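import numpy as np
import pytest

from nfspeech.corpus_io import Dataset, MedState, Transcript, load_nfs_items
from nfspeech.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def nfs_items():
    return load_nfs_items()


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (33 patients, paired ON/OFF)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-patient cohort for orchestration tests that loop over folds."""
    return generate_cohort(CohortConfig(n_patients=8, seed=3))


@pytest.fixture()
def tiny_dataset():
    return Dataset(
        transcripts=[
            Transcript("p1", "p1-OFF", MedState.OFF, "i feel tired and low", score=12.0),
            Transcript("p1", "p1-ON", MedState.ON, "i feel cheerful and strong", score=50.0),
            Transcript("p2", "p2-OFF", MedState.OFF, "i feel weary and sad", score=20.0),
            Transcript("p2", "p2-ON", MedState.ON, "i feel talkative and lively", score=44.0),
        ],
        provenance="test:tiny",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
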