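import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sevscore as sv

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def definitions():
    return sv.load_score_definitions()


@pytest.fixture(scope="session")
def registry():
    return sv.load_variable_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared read-only across tests."""
    return sv.generate_cohort(sv.CohortSpec(seed=0))


@pytest.fixture(scope="session")
def eligible_cohort(default_cohort):
    eligible, _ = sv.completeness_filter(default_cohort)
    return eligible


def normal_snapshot(registry, window="icu_24h_worst", **overrides):
    """Snapshot with every variable at its normal reference value."""
    values = {name: spec.normal for name, spec in registry.items()}
    values.update(overrides)
    return sv.PhysiologySnapshot(window=window, values=values,
                                 acute_renal_failure=False, ventilated=False)


def make_record(**overrides):
    base = dict(patient_id="T1", age=40, sex="female",
                admitting_service="medicine", micu=True,
                admission_category="nonoperative", medical_admission=True,
                unscheduled_surgery=False, chronic_flags=frozenset(),
                died_60d=False, died_inhospital=False)
    base.update(overrides)
    return sv.PatientRecord(**base)
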