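import pytest

from kerassign import (
    csi_reference_table,
    fur_reference_table,
    load_composition,
    load_topologies,
)


@pytest.fixture(scope="session")
def topologies():
    return load_topologies()


@pytest.fixture(scope="session")
def csi_refs():
    return csi_reference_table()


@pytest.fixture(scope="session")
def fur_refs():
    return fur_reference_table()


@pytest.fixture(scope="session")
def composition():
    return load_composition()


#: printed dCA - dCB indices of the observed fur assignment table
TABLE1_INDICES = {
    "S": -8, "P": 30, "L": 15, "R": 30, "Y": 18, "T": -2,
    "V": 33, "A": 27, "K": 23, "F": 18, "I": 27,
}

#: high-certainty (bold) secondary-structure calls of the observed table
TABLE1_BOLD_CLASSES = {"S": "S", "P": "S", "Y": "C", "T": "H", "V": "H", "F": "C"}

#: tentative rows' printed calls (agreement reported, not guaranteed)
TABLE1_TENTATIVE_CLASSES = {"L": "H", "R": "H", "A": "S", "K": "S", "I": "S"}
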