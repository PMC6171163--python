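import numpy as np
import pytest

from ctrlshare import StudyDesign, ThresholdSet


@pytest.fixture(scope="session")
def balanced_design():
    return StudyDesign(5000, 5000, 5000, 5000)


@pytest.fixture(scope="session")
def ra_design():
    """Cohort sizes of a large published rheumatoid-arthritis GWAS."""
    return StudyDesign(20169, 5539, 8806, 6768)


@pytest.fixture(scope="session")
def ftd_design():
    """Cohort sizes of a fronto-temporal dementia GWAS (weakly ascertained replication controls)."""
    return StudyDesign(4308, 2154, 5094, 1372)


@pytest.fixture(scope="session")
def k15_design():
    return StudyDesign(15000, 5000, 5000, 5000)


@pytest.fixture(scope="session")
def gwas_thresholds():
    return ThresholdSet(5e-6, 5e-4, 5e-8)


@pytest.fixture(scope="session")
def loose_thresholds():
    """Thresholds loose enough for plain Monte-Carlo to see hits."""
    return ThresholdSet(1e-2, 5e-2, 1e-2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_design(rng, lo=50, hi=50000):
    return StudyDesign(*(int(v) for v in rng.integers(lo, hi, size=4)))
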