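import numpy as np
import pytest

from sletraj.core import N_PARAMETERS, Cohort, PatientSeries


def make_patient(pid, values, sledai=None, days=None):
    """Build a patient from an (n_visits, 17) value array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    if values.shape[1] != N_PARAMETERS:
        raise ValueError("values must have 17 columns")
    if sledai is None:
        sledai = np.zeros(n)
    if days is None:
        days = np.arange(n) * 30
    return PatientSeries(patient_id=pid, days=np.asarray(days),
                         values=values, sledai=np.asarray(sledai, dtype=float))


def make_cohort(patient_values, normalized=False, characteristics=None,
                sledai=None):
    """Cohort from {pid: (n, 17) array}; optional per-patient SLEDAI arrays."""
    patients = [
        make_patient(pid, vals, sledai=None if sledai is None else sledai[pid])
        for pid, vals in patient_values.items()
    ]
    return Cohort(patients=patients, characteristics=characteristics or {},
                  normalized=normalized)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_normalized_cohort(rng):
    """6 patients x 4-6 visits of z-scale values, flagged normalized.

    Values are raw draws (not exactly pooled-z); suitable for tests that only
    need the flag and plausible scale, not the exact moments.
    """
    vals = {
        f"P{i}": rng.standard_normal((4 + i % 3, N_PARAMETERS)) for i in range(6)
    }
    sled = {pid: np.abs(np.round(4 + rng.standard_normal(v.shape[0])))
            for pid, v in vals.items()}
    return make_cohort(vals, normalized=True, sledai=sled)
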