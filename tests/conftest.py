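import numpy as np
import pytest

from contactbench.contact_map import Contact, ContactMap, classify_separation
from contactbench.rr_io import ScoredPair


def make_contact(i: int, j: int, distance: float = 5.0) -> Contact:
    return Contact(i=i, j=j, distance=distance, sep_class=classify_separation(i, j))


def make_map(pairs, length=100, target_id="T1", observed=None) -> ContactMap:
    return ContactMap(
        target_id=target_id,
        length=length,
        contacts=frozenset(make_contact(i, j) for i, j in pairs),
        observed=frozenset(observed) if observed is not None else None,
    )


def make_pair(i: int, j: int, score: float) -> ScoredPair:
    return ScoredPair(i=i, j=j, dmin=0.0, dmax=8.0, score=score)


def random_instance(rng: np.random.Generator, length: int = 60):
    """A random truth map and a random ranked selection over the same chain."""
    n_true = int(rng.integers(1, 15))
    all_pairs = [(i, j) for i in range(1, length + 1) for j in range(i + 1, length + 1)]
    idx = rng.choice(len(all_pairs), size=n_true, replace=False)
    truth = make_map([all_pairs[k] for k in idx], length=length)
    n_sel = int(rng.integers(1, 20))
    idx = rng.choice(len(all_pairs), size=n_sel, replace=False)
    scores = np.sort(rng.uniform(0.0, 1.0, size=n_sel))[::-1]
    selected = [
        make_pair(*all_pairs[k], score=float(s)) for k, s in zip(idx, scores)
    ]
    return truth, selected


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
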