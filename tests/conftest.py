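import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_1c(tmp_path_factory):
    """A small one-cell-regime simulation shared across tests."""
    from tailscape.synthetic_data import simulate_dataset, stage_preset

    cfg = stage_preset("1C", seed=123, n_genes=30)
    return simulate_dataset(cfg, tmp_path_factory.mktemp("sim1c"))


@pytest.fixture(scope="session")
def sim_gv_ref(tmp_path_factory):
    """Low-degradation reference sample with identical gene geometry to sim_1c."""
    from tailscape.synthetic_data import simulate_dataset, stage_preset

    cfg = stage_preset("GV", seed=123, n_genes=30)
    return simulate_dataset(cfg, tmp_path_factory.mktemp("simgv"))


@pytest.fixture(scope="session")
def gene_models(sim_1c):
    from tailscape.io_formats import read_gene_models

    return read_gene_models(sim_1c.gtf_path)


@pytest.fixture
def rng():
    return np.random.default_rng(20230116)
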