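import pytest

from vuscope import cohort, synth


@pytest.fixture(scope="session")
def table2_path():
    return cohort.packaged_fixture("table2.tsv")


@pytest.fixture(scope="session")
def table1_path():
    return cohort.packaged_fixture("table1.tsv")


@pytest.fixture(scope="session")
def helix():
    return synth.gen_structure("ideal_helix", {"length": 24})


@pytest.fixture(scope="session")
def dimer():
    return synth.gen_structure("toy_dimer", {"length": 16, "min_distance": 3.5})
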