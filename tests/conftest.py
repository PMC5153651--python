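import numpy as np
import pytest

from metanorm import preprocess as prep
from metanorm.datamodel import PeakTable
from metanorm.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def small_table(rng) -> PeakTable:
    """Complete positive 20x6 table, lognormal intensities."""
    x = np.exp(rng.normal(5, 1, (20, 6)))
    return PeakTable([f"f{i}" for i in range(20)], [f"s{j}" for j in range(6)], x)


@pytest.fixture(scope="session")
def default_synth():
    """One default-condition synthetic study, shared across tests."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def preprocessed_default(default_synth):
    table, meta, truth = default_synth
    imputed, log = prep.run(table, meta)
    return imputed, meta, truth, log


def proportional_table(rng, p=50, n=8) -> tuple[PeakTable, np.ndarray]:
    """Columns are exact dilutions d_j of one common spectrum."""
    spectrum = np.exp(rng.normal(5, 1, p))
    d = np.exp(rng.normal(0, 0.3, n))
    x = spectrum[:, None] * d[None, :]
    t = PeakTable([f"f{i}" for i in range(p)], [f"s{j}" for j in range(n)], x)
    return t, d
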