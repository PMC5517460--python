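import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from nirsnet import (
    ArtifactParams,
    CohortSpec,
    PipelineConfig,
    make_modular_covariance,
    simulate_run,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort: 3 subjects, 8 channels, 1 Hz — still 600 s so the
    full 19-bin duration grid applies.  Two strongly coupled modules keep
    nearly all sample correlations positive, so the sparsity grid up to 0.5
    is always satisfiable."""
    return CohortSpec(
        n_subjects=3, n_runs=2, n_channels=8, duration_s=600.0,
        sampling_rate_hz=1.0, rng_seed=11,
        ground_truth_covariance=make_modular_covariance(
            8, 2, within_r=0.6, between_r=0.35, seed=11, jitter=0.02),
        artifact_params=ArtifactParams.none(),
    )


@pytest.fixture(scope="session")
def artifact_run():
    """One 46-channel run with the default artifact content (5 Hz, 600 s)."""
    spec = CohortSpec(
        n_subjects=1, n_runs=1, n_channels=46, duration_s=600.0,
        sampling_rate_hz=5.0, rng_seed=21,
    )
    return simulate_run(spec, 0, 0)


@pytest.fixture(scope="session")
def clean_run():
    """One artifact-free 46-channel run (5 Hz, 600 s)."""
    spec = CohortSpec(
        n_subjects=1, n_runs=1, n_channels=46, duration_s=600.0,
        sampling_rate_hz=5.0, rng_seed=22,
        artifact_params=ArtifactParams.none(),
    )
    return simulate_run(spec, 0, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
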