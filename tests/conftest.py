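import numpy as np
import pytest

from maintpkpd.cohort import CohortConfig, generate_cohort
from maintpkpd.datasets import Dataset, DoseEvent, Observation, PatientRecord
from maintpkpd.params import load_profile


def make_patient(
    pid="p1",
    *,
    age=5.9,
    height=114.0,
    weight=21.5,
    horizon=56,
    d6=75.0,
    dmtx=20.0,
    obs=None,
):
    """A deterministic reference patient on the protocol starting schedule."""
    doses = [DoseEvent(float(t), "6MP", d6) for t in range(horizon) if d6 > 0]
    doses += [DoseEvent(float(t), "MTX", dmtx) for t in range(0, horizon, 7) if dmtx > 0]
    if obs is None:
        obs = [
            Observation(0.0, "E-MTX", 0.026),
            Observation(0.0, "E-TGN", 0.83),
            Observation(0.0, "ANC", 1.9),
            Observation(28.0, "E-MTX", 0.03),
            Observation(28.0, "E-TGN", 0.9),
            Observation(14.0, "ANC", 1.5),
            Observation(42.0, "ANC", 1.8),
        ]
    return PatientRecord(pid, age, height, weight, doses, obs)


@pytest.fixture(scope="session")
def reference_patient():
    return make_patient()

@pytest.fixture(scope="session")
def final_params():
    return load_profile("pkpd_final")


@pytest.fixture(scope="session")
def small_cohort():
    """Eight virtual patients over half a year; shared across tests."""
    cfg = CohortConfig(n_patients=8, seed=42, horizon=182)
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
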