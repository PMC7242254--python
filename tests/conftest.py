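import numpy as np
import pytest

from phscreen import (
    Diagnosis,
    PatientRecord,
    PHGroup,
    Sex,
    default_params,
    generate_cohort,
)


def make_record(**overrides) -> PatientRecord:
    """A valid baseline record; override any field per test."""
    base = dict(
        id="T001",
        age=55.0,
        sex=Sex.MALE,
        diagnosis=Diagnosis.IPF,
        pack_years=10.0,
        six_mwd=500.0,
        sat0=96.0,
        sat6=92.0,
        fev1_fvc=78.0,
        fvc_pct=95.0,
        vc_pct=97.0,
        tlc_pct=90.0,
        dlco_pct=60.0,
        ntprobnp=100.0,
        ph_group=None,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_params(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labelled_groups(default_cohort):
    a = [r for r in default_cohort if r.ph_group is PHGroup.A_LOW]
    b = [r for r in default_cohort if r.ph_group is PHGroup.B_INCREASED]
    return a, b
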