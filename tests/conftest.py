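import numpy as np
import pytest

from afp_ensemble import ProteinRecord, generate_bundle

AA = "ARNDCQEGHILKMFPSTWYV"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150907)


@pytest.fixture(scope="session")
def small_bundle():
    """Six labeled synthetic proteins with all annotation kinds."""
    return generate_bundle(3, 3, length_range=(50, 80), signal=0.5, seed=11)


@pytest.fixture()
def record_factory():
    def make(sequence: str, pid: str = "p1", label=None) -> ProteinRecord:
        return ProteinRecord(pid, sequence, label)

    return make
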