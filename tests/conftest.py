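import pytest

from ambiribo.synthetic import SimConfig, make_ambigram_genome


@pytest.fixture(scope="session")
def rdrp_segment():
    return make_ambigram_genome(3200, seed=1, seg_id="rdrp")


@pytest.fixture(scope="session")
def robin_segment():
    return make_ambigram_genome(800, seed=1, seg_id="robin")


@pytest.fixture()
def cfg():
    return SimConfig(seed=1)
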