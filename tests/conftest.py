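import pytest

from dsbrepair.pipeline import make_context
from dsbrepair.synthetic_data import make_construct

SENSE_SEED = 1
YEAST_SEED = 5


@pytest.fixture(scope="session")
def sense_spec():
    return make_construct(SENSE_SEED, name="sense")


@pytest.fixture(scope="session")
def branch_spec():
    return make_construct(SENSE_SEED, branch_deleted=True, name="sense")


@pytest.fixture(scope="session")
def yeast_spec():
    return make_construct(YEAST_SEED, exon1_len=104, intron_len=217, exon2_len=104,
                          branch_len=33, cut_offset_a=6, cut_offset_b=6,
                          organism_mode="yeast", name="yeast")


@pytest.fixture(scope="session")
def ctx_1dsb(sense_spec):
    return make_context(sense_spec, "sgA")


@pytest.fixture(scope="session")
def ctx_2dsb(sense_spec):
    return make_context(sense_spec, "sgU", "sgD", with_flip_probe=True)
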