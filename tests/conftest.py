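import random

import pytest

from wmdec.params import ModelParameters


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def rng():
    return random.Random(12345)


SMALL_DLTM = """\
CUE
GOAL
TSKSET
TARGET
MAGCAT
SMALL syllables=1 link=SUP:MAGCAT link=OPP:LARGE
LARGE syllables=1 link=SUP:MAGCAT
CMAG syllables=1 link=SUP:CUE link=PROP:MAG
MAG syllables=1 link=SUP:GOAL link=PROP:MAGTS
MAGTS link=SUP:TSKSET
D9 syllables=1 link=SUP:TARGET link=PROP:LARGE
D2 syllables=1 link=SUP:TARGET link=PROP:SMALL
"""


@pytest.fixture
def small_dltm():
    from wmdec.knowledge import load_dltm
    return load_dltm(SMALL_DLTM)
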