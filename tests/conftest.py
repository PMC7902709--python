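import numpy as np
import pytest

from mnox.orfs import Contig


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_contig(rng, length, contig_id="c1", with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    seq = "".join(rng.choice(list(alphabet), size=length, p=probs))
    return Contig(contig_id, seq)
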