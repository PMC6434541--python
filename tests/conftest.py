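from __future__ import annotations

import pytest

from phenoclim.config import AnalysisConfig
from phenoclim.pipeline import run_pipeline
from phenoclim.synthetic import SyntheticConfig, generate_experiment


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """Deterministic experiment, daily NDVI sampling: truth is recoverable
    exactly."""
    cfg = SyntheticConfig().zero_noise()
    return generate_experiment(cfg, seed=11, ndvi_sampling_interval_days=1)


@pytest.fixture(scope="session")
def default_experiment():
    """One experiment under the default study conditions (noise on)."""
    return generate_experiment(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_experiment):
    exp = default_experiment
    textures = {s: spec.texture for s, spec in exp.specs.items()}
    return run_pipeline(AnalysisConfig(), exp.design, exp.env, exp.ndvi,
                        exp.flowering, textures)
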