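import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A small study-shaped synthetic dataset shared across tests."""
    from genoerode import default_config, simulate_dataset

    cfg = default_config(
        seed=7,
        scaffolds=(("scaf01", 3_000_000), ("scaf02", 3_000_000)),
        n_sites=6000,
        n_genes=40,
        gene_length=10_000,
        inbreeding_f={"MalayPeninsula": 0.3, "Borneo": 0.05},
        ancestral_beta=1.0,
    )
    data, truth, _ = simulate_dataset(cfg)
    return cfg, data, truth
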