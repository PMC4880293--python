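import numpy as np
import pytest

from dyadhmm import ObservationDataset, perfect_profile
from dyadhmm.states import STATES

STATE_INDEX = {s: i for i, s in enumerate(STATES)}


@pytest.fixture
def perfect_bs():
    return perfect_profile("bs")


@pytest.fixture
def perfect_ox():
    return perfect_profile("ox")


def point_mass(state: str) -> np.ndarray:
    pi = np.zeros(9)
    pi[STATE_INDEX[state]] = 1.0
    return pi


def make_dataset(counts: dict, profiles: dict | None = None, locus: str = "test",
                 divisions_per_day: int = 1) -> ObservationDataset:
    """Dataset from {(day, treatment): [TT, TC, CT, CC]} with perfect default chemistry."""
    counts = {k: np.asarray(v, dtype=np.int64) for k, v in counts.items()}
    if profiles is None:
        profiles = {(day, tr): perfect_profile(tr, day=day) for day, tr in counts}
    return ObservationDataset(locus=locus, counts=counts, profiles=profiles,
                              divisions_per_day=divisions_per_day)


@pytest.fixture
def day0_dataset():
    """Balanced day-0-only dataset with perfect conversions."""
    return make_dataset({(0, "bs"): [50, 20, 20, 110], (0, "ox"): [120, 30, 30, 20]})
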