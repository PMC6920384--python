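import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_experiment():
    """One full default-condition simulation shared across test modules."""
    from sortramp import synthetic as syn

    return syn.simulate_experiment(syn.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_scores(default_experiment):
    from sortramp import scoring

    return [scoring.score_pipeline(m) for m in default_experiment.replicates]
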