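import numpy as np
import pytest

from limbscreen import AmpliconTarget, ReadLayout
from limbscreen.sim import DEFAULT_ADAPTER


def make_reference(seed: int = 7, length: int = 180) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def target():
    ref = make_reference()
    return AmpliconTarget(gene_name="gene1", reference_seq=ref, cut_site=90,
                          gene_primer=ref[:20])


@pytest.fixture
def layout():
    return ReadLayout(adapter_seq=DEFAULT_ADAPTER)
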