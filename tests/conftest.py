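import numpy as np
import pytest

from lampsim.annotations import TranscriptionUnit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tus():
    """Three units: a co-directional pair then a reverse unit."""
    return [
        TranscriptionUnit("t1", "chrS", 1_000, 2_000, "+",
                          fpkm_exon=10.0, fpkm_intron=10.0),
        TranscriptionUnit("t2", "chrS", 3_000, 6_000, "+",
                          fpkm_exon=2.0, fpkm_intron=2.0),
        TranscriptionUnit("t3", "chrS", 7_000, 9_000, "-",
                          fpkm_exon=5.0, fpkm_intron=5.0),
    ]
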