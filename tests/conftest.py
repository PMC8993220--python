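import pandas as pd
import pytest

from hydrop.barcode import build_whitelist
from hydrop.synth import SynthConfig, default_structure, make_plates, toy_genome


@pytest.fixture(scope="session")
def small_plates():
    """Three 8-well plates of 10-mers at min pairwise distance >= 3."""
    return make_plates(3, 8, 10, min_distance=3, seed=11)


@pytest.fixture(scope="session")
def small_whitelist(small_plates):
    return build_whitelist(small_plates)


@pytest.fixture(scope="session")
def structure():
    return default_structure(n_rounds=3, sub_length=10)


@pytest.fixture(scope="session")
def rna_structure():
    return default_structure(n_rounds=3, sub_length=10, umi_length=8)


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture()
def config():
    return SynthConfig(seed=7)


@pytest.fixture()
def toy_fragments():
    """Hand-sized fragments table spanning two barcodes."""
    rows = [
        ("chr1", 100, 200, "b1", 4),
        ("chr1", 300, 400, "b1", 1),
        ("chr1", 100, 200, "b2", 1),
        ("chr1", 500, 650, "b2", 2),
        ("chr2", 10, 90, "b2", 1),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
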