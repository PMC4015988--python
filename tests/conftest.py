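import numpy as np
import pytest

from crossbeta.builder import AggregateSpec, PeptideSpec, build_sheet
from crossbeta.config import AnalysisConfig


@pytest.fixture(scope="session")
def wt_sheet6():
    """Neutral-termini wild-type 6-mer, planar in-register."""
    return build_sheet(PeptideSpec("GNNQQNY", "neutral"), AggregateSpec(6))


@pytest.fixture(scope="session")
def charged_sheet5():
    return build_sheet(PeptideSpec("GNNQQNY", "charged"), AggregateSpec(5))


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
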