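import dataclasses

import numpy as np
import pytest

from tremordetect import CohortConfig

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    """A light cohort: 2 patients + 2 healthy, one 20-s trial each."""
    return CohortConfig(n_patients=2, n_healthy=2, n_trials=1,
                        trial_duration=20.0, seed=123)


@pytest.fixture(scope="session")
def clean_cfg() -> CohortConfig:
    """Noise-free, jitter-free configuration for exact constructions."""
    return CohortConfig(n_patients=1, n_healthy=1, n_trials=1,
                        trial_duration=10.0, angle_noise_deg=0.0,
                        drift_amp_deg=0.0, cycle_jitter=0.0,
                        physio_amp=0.0, seed=7)


@pytest.fixture(scope="session")
def medium_datasets():
    """Balanced 300-window datasets for all three modalities (shared)."""
    from tremordetect import build_datasets
    cfg = CohortConfig(n_patients=3, n_healthy=3, n_trials=2,
                       trial_duration=30.0, seed=42)
    return build_datasets(cfg, n_kin_per_class=150, n_emg_per_class=150)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
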