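import numpy as np
import pytest

from domainrates.io import Alignment, SequenceRecord
from domainrates.substitution import load_jtt, poisson_model

ALPHA = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="session")
def jtt():
    return load_jtt()


@pytest.fixture(scope="session")
def uniform_model():
    return poisson_model()


def states_to_str(states: np.ndarray) -> str:
    return "".join(ALPHA[s] for s in states)


def simulate_pair(model, t: float, n_sites: int, seed: int):
    """Ancestor from pi, descendant via P(t); returns two residue strings."""
    rng = np.random.default_rng(seed)
    a = rng.choice(20, size=n_sites, p=model.pi)
    P = model.transition_matrix(t)
    cum = P.cumsum(axis=1)
    b = (cum[a] < rng.random(n_sites)[:, None]).sum(axis=1)
    return states_to_str(a), states_to_str(b)


@pytest.fixture
def toy_alignment():
    return Alignment(
        [
            SequenceRecord("a", "MKVL"),
            SequenceRecord("b", "MKVI"),
            SequenceRecord("c", "MRVL"),
        ]
    )
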