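import pytest

from pufsf.motif_prediction import TRM, default_code_table
from pufsf.repeat_detection import default_profile


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def code_table():
    return default_code_table()


# TRM assignments that reconstruct the canonical complete Giardia Puf3-type
# motif 5'-UGUAUUUA-3' under the packaged code table (N->C repeat order).
GIPUF3_TRMS = [
    TRM("C", "R", "Q"),
    TRM("N", "Y", "Q"),
    TRM("N", "Y", "Q"),
    TRM("N", "Y", "Q"),
    TRM("C", "R", "Q"),
    TRM("N", "Y", "Q"),
    TRM("S", "N", "E"),
    TRM("N", "Y", "Q"),
]


@pytest.fixture(scope="session")
def gipuf3_trms():
    return list(GIPUF3_TRMS)
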