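import numpy as np
import pytest

from nmsitekit.synthetic import SyntheticSpec, generate
from nmsitekit.windows import LabeledWindow, WINDOW_LENGTH


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_windows(rng):
    """60 background windows, 10 positive / 50 negative, no planted signal."""
    spec = SyntheticSpec(n_pos=10, n_neg=50, motif_fidelity=0.25, seed=5)
    return generate(spec)


def make_window(sequence: str, label: int = 0, wid: str = "w0") -> LabeledWindow:
    assert len(sequence) == WINDOW_LENGTH
    return LabeledWindow(window_id=wid, sequence=sequence, label=label, origin=(wid, 21))


@pytest.fixture
def random_sequence(rng):
    def _make(n: int) -> str:
        return "".join(rng.choice(list("ACGU"), size=n))

    return _make
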