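import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heterosol import RunConfig, SimulationParams, run_pipeline, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_params() -> SimulationParams:
    """Small but fully structured cohort used across module tests."""
    return SimulationParams(
        n_orthogroups=12,
        protein_length_range=(60, 120),
        seed=7,
        frac_nonadditive=0.3,
        frac_solubility_shift=0.3,
        frac_biased=0.3,
    )


@pytest.fixture(scope="session")
def sim_dataset(tiny_params):
    return simulate_dataset(tiny_params)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-size (100 orthogroup) pipeline run."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run1"
    cfg = RunConfig()
    manifest = run_pipeline(cfg, outdir)
    return cfg, outdir, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
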