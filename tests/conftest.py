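import dataclasses

import numpy as np
import pytest

import xmittn as x
from xmittn.cohort import Diagnosis, LongitudinalVisit, Sex, SubjectRecord


def make_subject(subject_id="s1", diagnosis=Diagnosis.AD, **overrides):
    """A valid subject with sensible defaults, overridable per field."""
    base = dict(
        subject_id=subject_id,
        cohort_id="t",
        diagnosis=diagnosis,
        age=72.0,
        sex=Sex.MALE,
        education=14.0,
        apoe4_carrier=True,
        abeta42=140.0,
        ttau=120.0,
        ptau181=40.0,
        c3_raw=150000.0,
        fh=1600.0,
    )
    base.update(overrides)
    return SubjectRecord(**base)


def make_visits(months, exec_z=None, mem_z=None):
    exec_z = exec_z if exec_z is not None else [0.0] * len(months)
    mem_z = mem_z if mem_z is not None else [0.0] * len(months)
    return [
        LongitudinalVisit(months_from_baseline=m, executive_z=e, memory_z=z)
        for m, e, z in zip(months, exec_z, mem_z)
    ]


@pytest.fixture
def tiny_spec():
    """A small, fast cohort recipe sharing the standard structure."""
    base = x.adni_cohort_spec()
    groups = {
        d: dataclasses.replace(g, n=n)
        for (d, g), n in zip(base.groups.items(), (10, 14, 10))
    }
    return dataclasses.replace(base, groups=groups, cohort_id="tiny")


@pytest.fixture
def separable_toy():
    """24 points in 3 features, classes separated by ~4 SDs."""
    rng = np.random.default_rng(42)
    X0 = rng.normal(-2.0, 0.5, size=(12, 3))
    X1 = rng.normal(+2.0, 0.5, size=(12, 3))
    X = np.vstack([X0, X1])
    y = np.array([0] * 12 + [1] * 12)
    return X, y


@pytest.fixture
def adni_like_cohort():
    return x.normalize_c3(x.generate_cohort(x.adni_cohort_spec(), master_seed=11))
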