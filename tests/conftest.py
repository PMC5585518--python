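import numpy as np
import pytest

from impscore.registry import (
    ExclusionConfig,
    InjuryRecord,
    PatientRecord,
    apply_exclusions,
    parse_ais_code,
    split_dataset,
)
from impscore.simulate import GeneratorConfig, generate_registry


def make_patient(
    pid="P1",
    codes=("110000.3",),
    died=False,
    age=40,
    sex="male",
    mechanism="mvc",
    gcs=15,
    hospital="H0",
    los=3,
    **kwargs,
):
    injuries = tuple(InjuryRecord(parse_ais_code(c)) for c in codes)
    return PatientRecord(
        patient_id=pid,
        age=age,
        sex=sex,
        mechanism=mechanism,
        gcs=gcs,
        hospital_id=hospital,
        died=died,
        los_days=los,
        injuries=injuries,
        **kwargs,
    )


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture(scope="session")
def small_cohort():
    """A modest clean synthetic cohort shared across model/evaluation tests."""
    cfg = GeneratorConfig(n_patients=8000, seed=7, n_hospitals=8)
    patients, truth = generate_registry(cfg)
    retained, _ = apply_exclusions(
        patients, ExclusionConfig(min_hospital_volume=200)
    )
    return retained, truth


@pytest.fixture(scope="session")
def small_splits(small_cohort):
    patients, _ = small_cohort
    return split_dataset(patients, seed=11)


@pytest.fixture(scope="session")
def derived_small(small_splits):
    """Fitted stage-1 derivation on the small cohort's derivation split."""
    from impscore.wadp import WADPDeriver

    derivation, _, _ = small_splits
    return WADPDeriver(derivation).fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
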