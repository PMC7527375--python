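import numpy as np
import pytest

from retiscreen.cohort_io import PatientHistory, select_analysis_cohort
from retiscreen.imputation import ImputationScenario, apply_scenario
from retiscreen.risk_model import RiskModelParams, RiskProfile
from retiscreen.synthetic_cohort import CohortGenConfig, generate_cohort


@pytest.fixture(scope="session")
def params():
    return RiskModelParams()


@pytest.fixture(scope="session")
def small_synthetic():
    """400-patient generated cohort with the default study conditions."""
    return generate_cohort(CohortGenConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def analysis_cohort(small_synthetic):
    """Selected + imputed cohort with fast/slow onset maps."""
    kept, _ = select_analysis_cohort(small_synthetic.patients)
    imputed, onsets_fast = apply_scenario(kept, ImputationScenario("fast", 3))
    _, onsets_slow = apply_scenario(kept, ImputationScenario("slow", 3))
    return imputed, onsets_fast, onsets_slow


def make_history(
    grades,
    pid="P1",
    sex="female",
    spacing=12,
    hba1c=55.0,
    sbp=140.0,
    duration0=2.0,
    follow_up=None,
):
    """Hand-built history: one visit per grade entry (None = missing grade)."""
    n = len(grades)
    t = np.arange(n) * spacing
    return PatientHistory(
        patient_id=pid,
        sex=sex,
        follow_up_months=int(t[-1]) if follow_up is None else follow_up,
        t_months=t,
        grade=np.array([np.nan if g is None else float(g) for g in grades]),
        hba1c=np.full(n, float(hba1c)),
        sbp=np.full(n, float(sbp)),
        duration_years=duration0 + t / 12.0,
    )


def random_profiles(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        RiskProfile(
            male=bool(rng.integers(0, 2)),
            diabetes_duration_years=float(rng.uniform(0.1, 30.0)),
            hba1c=float(rng.uniform(30.0, 120.0)),
            sbp=float(rng.uniform(90.0, 200.0)),
            retinopathy_present=bool(rng.integers(0, 2)),
        )
        for _ in range(n)
    ]
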