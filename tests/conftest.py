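import numpy as np
import pytest

from normscreen import CohortSpec, GroupSpec, RegressionSpec, RetestSpec
from normscreen.cohort import SubjectRecord
from normscreen.simulate import generate_cohort, table1_spec


def make_record(**overrides) -> SubjectRecord:
    """A valid normal-cognition record; override fields as needed."""
    base = dict(
        id="S-0001", age=65.0, education_years=12.0, education_level="middle",
        sex="female", group="NC", mmse=28, adl=14, cdr_global=0.0,
        cdr_memory=0.0, his=1, hamd17=3, isr=30, dsr=27, dsr_retest=None,
    )
    base.update(overrides)
    return SubjectRecord(**base)


def nc_group(n=249, **overrides) -> GroupSpec:
    base = dict(label="NC", n=n, age_mean=66.94, age_sd=8.87, edu_mean=12.89,
                edu_sd=3.30, isr_mean=30.03, isr_sd=8.58, dsr_mean=26.60,
                dsr_sd=8.49, mmse_mean=28.41, mmse_sd=1.50)
    base.update(overrides)
    return GroupSpec(**base)


def mci_group(n=134, **overrides) -> GroupSpec:
    base = dict(label="MCI", n=n, age_mean=69.91, age_sd=8.38, edu_mean=11.32,
                edu_sd=3.84, isr_mean=13.91, isr_sd=8.79, dsr_mean=9.40,
                dsr_sd=8.88, mmse_mean=26.98, mmse_sd=2.04)
    base.update(overrides)
    return GroupSpec(**base)


@pytest.fixture(scope="session")
def table1():
    return table1_spec()


@pytest.fixture(scope="session")
def cohort(table1):
    """One full-size simulated cohort under the packaged study conditions."""
    return generate_cohort(table1, seed=20140310)


@pytest.fixture(scope="session")
def nc_cohort_large():
    """A large control-only cohort for moment/coefficient recovery checks."""
    spec = CohortSpec(
        groups=[nc_group(n=20000)],
        nc_regression=RegressionSpec(31.535, 0.746, -0.206, 7.9171),
        seed=7,
    )
    return generate_cohort(spec)
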