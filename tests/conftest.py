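import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from holoest import report, synthio  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_sim():
    """One seeded simulation at desk scale, shared across the suite."""
    return synthio.simulate(synthio.default_config(seed=7, reads_per_sample=40))


@pytest.fixture(scope="session")
def pipeline_bundle(default_sim, tmp_path_factory):
    """The full pipeline (clustering excluded; covered by its own tests)
    run once on the shared simulation."""
    params = report.PipelineParams(run_clustering=False)
    outdir = tmp_path_factory.mktemp("pipeline")
    return report.run_pipeline(default_sim, outdir, params)
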