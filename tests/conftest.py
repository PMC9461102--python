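import numpy as np
import pytest

from pekakit.enrichment_core import EnrichmentConfig, run_peka
from pekakit.synthetic_fixtures import FixtureConfig, generate_fixture
from pekakit.thresholding import ThresholdConfig


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted-motif dataset: 100 kb genome, 500 signal
    crosslinks with UGUGU planted at center offsets -2..+2, 5000 background."""
    return generate_fixture(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_fixture):
    fx = default_fixture
    return run_peka(
        fx.crosslinks,
        fx.peaks,
        fx.genome,
        fx.segmentation,
        "genome",
        EnrichmentConfig(seed=1),
        ThresholdConfig(seed=1),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_genome():
    from pekakit.formats_io import Genome

    return Genome({"chr1": "ACGTACGTAC"})
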