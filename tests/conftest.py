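import numpy as np
import pytest

from tilscape.slide_model import NucleusRecord, NucleusType, RegionMaskSet


@pytest.fixture
def rng():
    return np.random.default_rng(20230930)


def make_masks(shape=(64, 64), tumour=None, stroma=None, dcis=None, excluded=None,
               tissue=None) -> RegionMaskSet:
    """Build a RegionMaskSet from optional boolean arrays (zeros by default,
    tissue defaults to all-true)."""
    z = np.zeros(shape, dtype=bool)
    return RegionMaskSet(
        {
            "tissue": np.ones(shape, dtype=bool) if tissue is None else tissue,
            "tumour": z if tumour is None else tumour,
            "stroma": z if stroma is None else stroma,
            "dcis": z if dcis is None else dcis,
            "excluded": z if excluded is None else excluded,
        }
    )


def nucleus(x, y, ntype="immune", area=None, nid=None):
    return NucleusRecord(
        nid or f"n_{ntype}_{x}_{y}", float(x), float(y), NucleusType(ntype), area
    )


@pytest.fixture
def square_tumour_masks():
    """20x20 tumour square centred in a 96x96 field of uniform stroma."""
    shape = (96, 96)
    tumour = np.zeros(shape, dtype=bool)
    tumour[38:58, 38:58] = True
    stroma = ~tumour
    return make_masks(shape, tumour=tumour, stroma=stroma)
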