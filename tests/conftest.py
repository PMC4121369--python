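import pytest
from hypothesis import settings

from xxyomics import SimulationConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort shared across tests: 20 reference individuals
    (10 per sex) plus a 47,XXY index case, default noise."""
    return simulate_cohort(SimulationConfig(n_individuals=20, seed=11))


@pytest.fixture(scope="session")
def pipeline_report(default_cohort, tmp_path_factory):
    from xxyomics import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(PipelineConfig(out_dir=str(out)), cohort=default_cohort)
    return report, out
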