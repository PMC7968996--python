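import numpy as np
import pytest

from tfparalog.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return {"chr1": seq}


def make_set(pairs, chrom="chr1"):
    return IntervalSet(GenomicInterval(chrom, s, e) for s, e in pairs)
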