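import warnings

import pytest

from necropop.io import packaged_data, read_frequency_table, read_isotope_table
from necropop.isotopes import LocalRange
from necropop.records import AnalysisConfig

# The three most extreme positions on MDS axis 1 and the Ward 2-cut both
# isolate these groups in the reference analysis.
CELTS = {"BRIT", "MunRain", "HalD"}
ITALICS = [
    "LAA", "LAB", "LAC", "ETB", "ETC", "PCB", "PCC",
    "CAA", "CAB", "CAC", "SUL", "SAM", "MON",
]


@pytest.fixture(scope="session")
def isotope_samples():
    return read_isotope_table(packaged_data("table2_isotopes.csv"))


@pytest.fixture(scope="session")
def frequency_groups():
    with warnings.catch_warnings():
        # three printed percent/n cells are internally inconsistent; the
        # reader warns and recovers the nearest count
        warnings.simplefilter("ignore", UserWarning)
        groups, panel = read_frequency_table(packaged_data("table4_frequencies.csv"))
    return {g.group: g for g in groups}, panel


@pytest.fixture(scope="session")
def local_range():
    return LocalRange(0.7086, 0.7090)


@pytest.fixture
def config():
    return AnalysisConfig(n_permutations=499, rf_n_trees=200, seed=11)
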