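import numpy as np
import pytest

from loxscreen import RbeVariant, TruthRecord
from loxscreen.simulate import draw_markers


@pytest.fixture(scope="session")
def markers():
    return draw_markers(42)


@pytest.fixture(scope="session")
def wt_variant():
    return RbeVariant("TATACGAAGTTAT")


@pytest.fixture()
def small_truth(wt_variant):
    """Three variants with well-separated true rates, modest depth."""
    return [
        TruthRecord(wt_variant, 0.035, 0.5, 800),
        TruthRecord(RbeVariant("GATGTCAAGATAG"), 0.035, 0.173, 800),
        TruthRecord(RbeVariant("AAAACGAAGTTAT"), 0.035, 0.297, 800),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
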