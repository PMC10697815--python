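import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic cohort run through the whole pipeline."""
    from cnvpqtl.pipeline import run_synthetic_pipeline
    from cnvpqtl.synthetic_data import default_sim_config

    config = default_sim_config(seed=0)
    result, truth = run_synthetic_pipeline(config)
    return config, result, truth
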