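import numpy as np
import pytest

from lungntcp import Cohort, DoseVolumeHistogram, PatientRecord
from lungntcp.simulate import CohortSpec, generate_cohort


def random_differential_dvh(rng: np.random.Generator, max_bins: int = 12) -> DoseVolumeHistogram:
    """A random valid differential DVH (used by several property tests)."""
    k = int(rng.integers(1, max_bins + 1))
    doses = np.sort(rng.uniform(0.5, 60.0, size=k))
    while np.any(np.diff(doses) <= 0):  # enforce strict increase
        doses = np.sort(rng.uniform(0.5, 60.0, size=k))
    vols = rng.dirichlet(np.ones(k))
    return DoseVolumeHistogram(doses, vols, "differential")


def uniform_dvh(dose_gy: float) -> DoseVolumeHistogram:
    """Whole organ uniformly irradiated at one dose."""
    return DoseVolumeHistogram(np.array([dose_gy]), np.array([1.0]), "differential")


def make_record(pid: str, dvh: DoseVolumeHistogram, grade: int = 0) -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        dvh=dvh,
        age_years=50,
        chemo_cycles=4,
        surgery="breast_conserving",
        stage="II",
        rili_grade=grade,
    )


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A quick 120-patient synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n_patients=120, seed=11))
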