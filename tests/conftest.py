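import numpy as np
import pytest

from ctdnakin.cohort import PatientRecord, prepare_cohort
from ctdnakin.kinetics.models import EffectVector, one_step, three_step, two_step
from ctdnakin.population import build_effect_structure
from ctdnakin.synthetic import CohortConfig, generate_cohort

ALL_MODELS = (one_step(), two_step(), three_step())


@pytest.fixture(scope="session")
def generic_params():
    return EffectVector(
        B0=5e11, c0pb=1e9, gamma_d=0.5, s_c=2.0, alpha=1e-3, gamma_t=2.0
    )


@pytest.fixture(scope="session")
def day_grid():
    return np.linspace(0.0, 21.0, 40)


def random_effect_vector(rng) -> EffectVector:
    """Log-uniform draw over the documented physiologic bounds."""
    return EffectVector(
        B0=10 ** rng.uniform(10, 12),
        c0pb=10 ** rng.uniform(4, 9),
        gamma_d=10 ** rng.uniform(-1, 1),
        s_c=1.0 + 10 ** rng.uniform(-1, 1),
        alpha=10 ** rng.uniform(-4, 0),
        gamma_t=10 ** rng.uniform(-1, 1.2),
    )


def tiny_records(n=3):
    """Hand-made raw records exercising the preprocessing rules."""
    out = []
    for i in range(n):
        out.append(
            PatientRecord(
                patient_id=f"P{i + 1}",
                mutation="NPM1" if i % 2 == 0 else "IDH2",
                relapse=(i == 0),
                blast_obs=[(-4.0 + i, 0.6), (16.0 + i % 3, 0.05 * i)],
                ctdna_obs=[(0.0, 2.0e5), (2.0, 9.0e4), (8.0, 1.5e4)],
                blood_volume=4.0 + 0.5 * i,
            )
        )
    return out


@pytest.fixture()
def small_cohort():
    """Prepared 6-patient synthetic cohort (fast fixture for fitting tests)."""
    cfg = CohortConfig(n_patients=6, seed=42, relapse_fraction=0.0)
    truth, records = generate_cohort(cfg)
    return truth, prepare_cohort(records)


@pytest.fixture(scope="session")
def three_step_structure():
    return build_effect_structure(three_step())
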