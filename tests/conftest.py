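import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gated_dataset():
    """Strongly gated planted triples: 10 planted + 90 null candidate pairs, n=300."""
    from gdnet.simulate import GeneratorConfig, generate_dependency_dataset

    cfg = GeneratorConfig(
        n_samples=300, n_genes=220, n_modulated_pairs=10, n_null_pairs=90,
        gate_strength=1.0, active_side="low", seed=7,
    )
    return cfg, generate_dependency_dataset(cfg)


@pytest.fixture(scope="session")
def survival_family():
    """Three cohorts sharing 5 planted hazard genes (beta 0.6) among 50 genes."""
    from gdnet.simulate import GeneratorConfig, generate_survival_family

    cfg = GeneratorConfig(
        n_samples=200, n_genes=50, n_hazard_genes=5, hazard_beta=0.6,
        n_datasets=3, seed=11,
    )
    return cfg, generate_survival_family(cfg)
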