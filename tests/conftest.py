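import numpy as np
import pytest

from tepqual.quality import load_fixture_table, paired_comprehensive_data, records_to_frame


@pytest.fixture(scope="session")
def table5_records():
    return load_fixture_table("table5")


@pytest.fixture(scope="session")
def table5_frame(table5_records):
    return records_to_frame(table5_records)


@pytest.fixture(scope="session")
def table2_records():
    return load_fixture_table("table2")


@pytest.fixture(scope="session")
def comprehensive_pairs():
    """The 21 (TEP, comprehensive TOPSIS score) calibration pairs."""
    return paired_comprehensive_data()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240615)
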