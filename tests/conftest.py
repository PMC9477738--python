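import pytest

from cobind.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset shared across read-only tests."""
    return simulate_all(SimConfig(seed=7))


@pytest.fixture()
def small_pipeline_config():
    """A fast simulate-first pipeline config for orchestration tests."""
    from cobind.pipeline import default_config

    cfg = default_config()
    cfg["simulate"] = {
        "n_chrom": 2,
        "chrom_length": 200_000,
        "n_genes": 120,
        "n_peaks": 200,
        "n_cooperative": 5,
        "n_shared_degs": 12,
        "deg_plans": {"pif4": {"n_deg": 40}, "cdfq": {"n_deg": 40}},
    }
    cfg["annotation"]["n_sets"] = 10
    return cfg
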