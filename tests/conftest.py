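import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_simulation():
    """One default-preset simulation shared by the slower analysis tests."""
    from fyvepx.simulate import generate, preset_default

    config = preset_default(seed=11)
    records, hits, lineage, ledger = generate(config)
    return config, records, hits, lineage, ledger


@pytest.fixture(scope="session")
def preset_pipeline(preset_simulation):
    from fyvepx.pipeline import run

    _, records, hits, lineage, _ = preset_simulation
    return run(records, hits, lineage)
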