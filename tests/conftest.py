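import pytest

from oleomics import feature_io, synthdata


@pytest.fixture(scope="session")
def table1():
    return feature_io.load_table1_fixture()


@pytest.fixture(scope="session")
def table3():
    return feature_io.load_table3_fixture()


@pytest.fixture(scope="session")
def table4():
    return feature_io.load_table4_fixture()


@pytest.fixture(scope="session")
def small_library(table1):
    return table1[:8]


@pytest.fixture(scope="session")
def synth_default(small_library):
    return synthdata.simulate_feature_tables(small_library, seed=42)


@pytest.fixture()
def toy_feature():
    def make(fid="f1", mz=153.0558, rt=170.0, polarity="-", intensities=None):
        return feature_io.Feature(
            fid, mz, rt, polarity,
            intensities or {"s1": 10.0, "s2": 20.0, "s3": 30.0, "s4": 40.0})
    return make
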