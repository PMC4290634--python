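import numpy as np
import pytest

from glycmotif.seqdata import SequenceFragment, WindowConfig


@pytest.fixture(scope="session")
def window():
    return WindowConfig()


def make_frag(window_str: str, protein_id: str = "P1", position: int = 6,
              label: str = "positive") -> SequenceFragment:
    """Build a fragment straight from an 11-character window string."""
    n = len(window_str) // 2
    return SequenceFragment(window_str, n, protein_id, position, label)


@pytest.fixture
def frag_factory():
    return make_frag


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_windows():
    """200 random 11-mers with an S/T center (seeded, session-wide)."""
    from glycmotif.seqdata import AMINO_ACIDS

    gen = np.random.default_rng(99)
    out = []
    for k in range(200):
        chars = gen.choice(list(AMINO_ACIDS), size=11)
        chars[5] = "S" if gen.random() < 0.5 else "T"
        out.append(make_frag("".join(chars), f"P{k}", 6))
    return out


@pytest.fixture(scope="session")
def bench_data():
    """One synthetic 3-class benchmark dataset, shared across tests."""
    from glycmotif.benchmark import benchmark_config
    from glycmotif.simulate import make_dataset

    return make_dataset(benchmark_config(0))
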