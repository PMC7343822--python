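import numpy as np
import pytest

from forestagb import (
    SyntheticForestConfig,
    generate_plots,
    generate_taxon_table,
)
from forestagb.config import load_config
from forestagb.validate import calibrate_correction_model


@pytest.fixture(scope="session")
def taxon_pool():
    return tuple(generate_taxon_table(50, seed=123))


@pytest.fixture(scope="session")
def forest_config(taxon_pool):
    return SyntheticForestConfig(taxon_pool=taxon_pool, seed=1)


@pytest.fixture(scope="session")
def plots20(forest_config):
    """Twenty default 0.5-ha synthetic reference plots."""
    return generate_plots(forest_config, 20, master_seed=42)


@pytest.fixture(scope="session")
def ref_plot(plots20):
    return plots20[0]


@pytest.fixture(scope="session")
def pipeline_config():
    return load_config(None)


@pytest.fixture(scope="session")
def correction_model(forest_config):
    calib = generate_plots(forest_config, 300, master_seed=7)
    return calibrate_correction_model(calib)
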