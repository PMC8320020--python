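import numpy as np
import pytest

from wearcast.synthetic import SyntheticCohortConfig, generate_participant


@pytest.fixture(scope="session")
def default_participant():
    """One seeded 120-day participant with a phase-locked 7-day cycle."""
    cfg = SyntheticCohortConfig(
        duration_days=120.0, seizure_rate=8.0 / 30.0,
        locking_kappa=(0.0, 3.0), seed=42)
    return generate_participant(cfg)


@pytest.fixture()
def quiet_config():
    """Noise- and dip-free config: the heart rate is a pure sum of sinusoids."""
    return SyntheticCohortConfig(
        duration_days=30.0, noise_sd=0.0, nocturnal_dip=0.0,
        missing_fraction=0.0, seizure_rate=0.0, seed=7)


def circ_mean_diff(a, b):
    """Absolute circular difference between two angle arrays."""
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))
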