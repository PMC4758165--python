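"""Synthetic two-cohort generator for the staging pipeline.

Real training (multi-center, n=230 MCI-AD/AD plus 115 normals) and test
(single-center, n=73 plus 25 normals) cohorts are access-restricted, so
this module draws statistically matched stand-ins: class-conditional
normal (truncated at zero) analyte distributions with the published
group means and SDs, Bernoulli sex/APOE e4 mixes, an age -> log-C3
gradient (older subjects run higher C3) and an age -> FH gradient
confined to biomarker-positive groups, a cohort-level multiplicative C3
assay factor emulating the between-platform shift that per-cohort
z-scoring must remove, and linear-trajectory longitudinal cognitive
visits with subject-level random intercepts and slopes.

Every MCI-AD subject is redrawn (rejection sampling) until the CSF
t-Tau/Abeta42 ratio meets the 0.39 inclusion rule, so generated cohorts
satisfy the data-model invariants by construction. The stated group
(mean, SD) pairs are the *marginal* moments: the age-gradient share of
the variance is carved out of the stated SD rather than added on top,
so generated group moments match the specification directly. Everything
is reproducible from a single master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import (
    AD_RATIO_THRESHOLD,
    Cohort,
    Diagnosis,
    LongitudinalVisit,
    Sex,
    SubjectRecord,
)
from .exceptions import ConfigurationError, RejectionBudgetError

#: Location/scale of log C3 (natural log of pg/mL) in the cognitively
#: normal reference population. The raw scale is arbitrary for the
#: pipeline — per-cohort z-scoring removes it — but a plausible assay
#: magnitude is used so generated files look like real exports.
LOG_C3_REF_MEAN = float(np.log(150_000.0))
LOG_C3_REF_SD = 0.45


@dataclass(frozen=True)
class GroupSpec:
    """Marginal distributions of one diagnosis group."""

    n: int
    age_mean: float
    age_sd: float
    pct_male: float            # percent, 0-100
    pct_apoe4: float           # percent, 0-100
    education_mean: float
    education_sd: float
    abeta42_mean: float
    abeta42_sd: float
    ttau_mean: float
    ttau_sd: float
    ptau181_mean: float
    ptau181_sd: float
    fh_mean: float
    fh_sd: float
    log_c3_mean: float
    log_c3_sd: float
    exec_baseline: float = 0.0
    exec_slope: float = 0.0    # Z per month
    mem_baseline: float = 0.0
    mem_slope: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    cohort_id: str
    groups: dict[Diagnosis, GroupSpec]
    #: ln(pg/mL) change in C3 per year of age, within group.
    age_coef_log_c3: float = 0.015
    #: pg/mL change in FH per year of age, biomarker-positive groups only.
    age_coef_fh: float = 12.0
    #: Restrict the FH age gradient to MCI-AD/AD (diagnosis x age
    #: interaction): age leaves FH flat when CSF AD biomarkers are normal.
    fh_age_interaction: bool = True
    #: Multiplicative cohort-level C3 assay factor (platform shift).
    c3_assay_factor: float = 1.0
    visit_months: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    #: Which groups receive longitudinal visits.
    visit_groups: tuple[Diagnosis, ...] = (Diagnosis.MCI_AD, Diagnosis.AD)
    #: Groups whose subjects are redrawn until t-Tau/Abeta42 >= 0.39.
    #: MCI-AD always is (inclusion rule); null/staged scenarios add AD so
    #: the truncation itself cannot act as class signal.
    ratio_constrained_groups: tuple[Diagnosis, ...] = (Diagnosis.MCI_AD,)
    baseline_sd: float = 0.5   # between-subject intercept SD, Z units
    slope_sd: float = 0.01     # between-subject slope SD, Z/month
    resid_sd: float = 0.3      # within-subject visit noise SD, Z units
    master_seed: int = 0
    rejection_cap: int = 10_000


def _z_to_log_c3(z_mean: float, z_sd: float) -> tuple[float, float]:
    """Group log-C3 (mean, SD) from its z-score summary vs the reference."""
    return LOG_C3_REF_MEAN + z_mean * LOG_C3_REF_SD, z_sd * LOG_C3_REF_SD


def adni_cohort_spec() -> CohortSpec:
    """Multi-center training-cohort recipe (published group summaries).

    Group sizes 135 MCI-AD / 95 AD / 115 normals; analyte means and SDs
    per the published cohort table; group z-scored log-C3 summaries
    (-0.060 +/- 0.929 MCI-AD, +0.061 +/- 1.084 AD) mapped onto the
    reference log-C3 scale. Normal-group parameters are not published at
    this granularity and are set to values typical of amyloid-negative
    older controls.
    """
    mci_logc3 = _z_to_log_c3(-0.060, 0.929)
    ad_logc3 = _z_to_log_c3(0.061, 1.084)
    groups = {
        Diagnosis.NORMAL: GroupSpec(
            n=115, age_mean=75.0, age_sd=5.5, pct_male=50.0, pct_apoe4=27.0,
            education_mean=16.0, education_sd=2.8,
            abeta42_mean=210.0, abeta42_sd=50.0,
            ttau_mean=65.0, ttau_sd=28.0,
            ptau181_mean=24.0, ptau181_sd=11.0,
            fh_mean=1600.0, fh_sd=600.0,
            log_c3_mean=LOG_C3_REF_MEAN, log_c3_sd=LOG_C3_REF_SD,
        ),
        Diagnosis.MCI_AD: GroupSpec(
            n=135, age_mean=74.7, age_sd=7.6, pct_male=100 * 86 / 135,
            pct_apoe4=100 * 86 / 135,
            education_mean=15.8, education_sd=2.9,
            abeta42_mean=136.7, abeta42_sd=31.4,
            ttau_mean=122.8, ttau_sd=60.6,
            ptau181_mean=42.4, ptau181_sd=16.1,
            fh_mean=1568.0, fh_sd=629.0,
            log_c3_mean=mci_logc3[0], log_c3_sd=mci_logc3[1],
            exec_baseline=-0.5, exec_slope=-0.020,
            mem_baseline=-1.0, mem_slope=-0.025,
        ),
        Diagnosis.AD: GroupSpec(
            n=95, age_mean=74.3, age_sd=7.7, pct_male=100 * 53 / 95,
            pct_apoe4=100 * 67 / 95,
            education_mean=14.9, education_sd=3.1,
            abeta42_mean=143.5, abeta42_sd=39.9,
            ttau_mean=122.5, ttau_sd=57.8,
            ptau181_mean=41.4, ptau181_sd=19.9,
            fh_mean=1750.0, fh_sd=835.0,
            log_c3_mean=ad_logc3[0], log_c3_sd=ad_logc3[1],
            exec_baseline=-1.2, exec_slope=-0.045,
            mem_baseline=-1.8, mem_slope=-0.050,
        ),
    }
    return CohortSpec(cohort_id="train", groups=groups, c3_assay_factor=1.0)


def emory_cohort_spec() -> CohortSpec:
    """Single-center test-cohort recipe (published group summaries).

    Group sizes 51 MCI-AD / 22 AD / 25 normals; the C3 assay factor is
    below 1 because the test platform reads C3 systematically lower —
    the shift that per-cohort z-scoring is required to absorb.
    """
    mci_logc3 = _z_to_log_c3(-0.481, 1.031)
    ad_logc3 = _z_to_log_c3(-0.064, 0.784)
    groups = {
        Diagnosis.NORMAL: GroupSpec(
            n=25, age_mean=68.0, age_sd=8.0, pct_male=48.0, pct_apoe4=25.0,
            education_mean=16.0, education_sd=2.5,
            abeta42_mean=220.0, abeta42_sd=55.0,
            ttau_mean=60.0, ttau_sd=25.0,
            ptau181_mean=28.0, ptau181_sd=12.0,
            fh_mean=1600.0, fh_sd=500.0,
            log_c3_mean=LOG_C3_REF_MEAN, log_c3_sd=LOG_C3_REF_SD,
        ),
        Diagnosis.MCI_AD: GroupSpec(
            n=51, age_mean=69.0, age_sd=7.4, pct_male=100 * 28 / 51,
            pct_apoe4=100 * 25 / 51,
            education_mean=15.4, education_sd=2.5,
            abeta42_mean=129.8, abeta42_sd=55.3,
            ttau_mean=97.7, ttau_sd=49.6,
            ptau181_mean=55.6, ptau181_sd=25.7,
            fh_mean=1594.0, fh_sd=493.0,
            log_c3_mean=mci_logc3[0], log_c3_sd=mci_logc3[1],
            exec_baseline=-0.5, exec_slope=-0.020,
            mem_baseline=-1.0, mem_slope=-0.025,
        ),
        Diagnosis.AD: GroupSpec(
            n=22, age_mean=65.6, age_sd=8.8, pct_male=100 * 6 / 22,
            pct_apoe4=100 * 8 / 22,
            education_mean=13.9, education_sd=2.4,
            abeta42_mean=168.3, abeta42_sd=104.0,
            ttau_mean=120.3, ttau_sd=60.0,
            ptau181_mean=61.1, ptau181_sd=26.2,
            fh_mean=1692.0, fh_sd=474.0,
            log_c3_mean=ad_logc3[0], log_c3_sd=ad_logc3[1],
            exec_baseline=-1.2, exec_slope=-0.045,
            mem_baseline=-1.8, mem_slope=-0.050,
        ),
    }
    return CohortSpec(cohort_id="test", groups=groups, c3_assay_factor=0.6)


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from N(mean, sd) truncated below at 0 (analytes are positive)."""
    if sd == 0:
        if mean <= 0:
            raise ConfigurationError("degenerate analyte spec with mean <= 0")
        return mean
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _carve_sd(marginal_sd: float, structured_sd: float, what: str) -> float:
    """Residual SD once a structured (age-gradient) component is carved out."""
    resid_var = marginal_sd**2 - structured_sd**2
    if marginal_sd > 0 and resid_var <= 0:
        raise ConfigurationError(
            f"{what}: age-gradient variance exceeds the stated marginal SD"
        )
    return float(np.sqrt(max(resid_var, 0.0)))


def _draw_subject(
    rng: np.random.Generator,
    spec: CohortSpec,
    group: GroupSpec,
    diagnosis: Diagnosis,
    subject_id: str,
) -> SubjectRecord:
    age = float(rng.normal(group.age_mean, group.age_sd))
    age = max(age, 1.0)
    sex = Sex.MALE if rng.random() < group.pct_male / 100.0 else Sex.FEMALE
    apoe4 = bool(rng.random() < group.pct_apoe4 / 100.0)
    education = max(float(rng.normal(group.education_mean, group.education_sd)), 0.0)

    age_centered = age - group.age_mean
    fh_age = spec.age_coef_fh if (
        not spec.fh_age_interaction or diagnosis in (Diagnosis.MCI_AD, Diagnosis.AD)
    ) else 0.0
    fh_resid_sd = _carve_sd(group.fh_sd, abs(fh_age) * group.age_sd, "fh")
    fh = _trunc_normal(rng, group.fh_mean + fh_age * age_centered, fh_resid_sd)

    c3_resid_sd = _carve_sd(
        group.log_c3_sd, abs(spec.age_coef_log_c3) * group.age_sd, "log_c3"
    )
    log_c3 = rng.normal(
        group.log_c3_mean + spec.age_coef_log_c3 * age_centered, c3_resid_sd
    )
    c3_raw = float(np.exp(log_c3) * spec.c3_assay_factor)

    ptau181 = _trunc_normal(rng, group.ptau181_mean, group.ptau181_sd)
    constrained = (
        diagnosis is Diagnosis.MCI_AD or diagnosis in spec.ratio_constrained_groups
    )
    if constrained:
        for _ in range(spec.rejection_cap):
            abeta42 = _trunc_normal(rng, group.abeta42_mean, group.abeta42_sd)
            ttau = _trunc_normal(rng, group.ttau_mean, group.ttau_sd)
            if ttau / abeta42 >= AD_RATIO_THRESHOLD:
                break
        else:
            raise RejectionBudgetError(
                f"{subject_id}: could not satisfy t-Tau/Abeta42 >= "
                f"{AD_RATIO_THRESHOLD} within {spec.rejection_cap} draws"
            )
    else:
        abeta42 = _trunc_normal(rng, group.abeta42_mean, group.abeta42_sd)
        ttau = _trunc_normal(rng, group.ttau_mean, group.ttau_sd)

    visits: list[LongitudinalVisit] = []
    if diagnosis in spec.visit_groups and spec.visit_months:
        exec_b = rng.normal(group.exec_baseline, spec.baseline_sd)
        exec_s = rng.normal(group.exec_slope, spec.slope_sd)
        mem_b = rng.normal(group.mem_baseline, spec.baseline_sd)
        mem_s = rng.normal(group.mem_slope, spec.slope_sd)
        for m in spec.visit_months:
            visits.append(LongitudinalVisit(
                months_from_baseline=float(m),
                executive_z=float(exec_b + exec_s * m + rng.normal(0, spec.resid_sd)),
                memory_z=float(mem_b + mem_s * m + rng.normal(0, spec.resid_sd)),
            ))

    return SubjectRecord(
        subject_id=subject_id,
        cohort_id=spec.cohort_id,
        diagnosis=diagnosis,
        age=age,
        sex=sex,
        education=education,
        apoe4_carrier=apoe4,
        abeta42=abeta42,
        ttau=ttau,
        ptau181=ptau181,
        c3_raw=c3_raw,
        fh=fh,
        visits=visits,
    )


def generate_cohort(spec: CohortSpec, master_seed: int | None = None) -> Cohort:
    """Draw one cohort from a spec; byte-reproducible from the seed.

    The normal-reference group is the cohort's own NORMAL subjects.
    """
    seed = spec.master_seed if master_seed is None else master_seed
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0)))
    subjects: list[SubjectRecord] = []
    for diagnosis in (Diagnosis.NORMAL, Diagnosis.MCI_AD, Diagnosis.AD):
        group = spec.groups.get(diagnosis)
        if group is None or group.n == 0:
            continue
        for i in range(group.n):
            subjects.append(_draw_subject(
                rng, spec, group, diagnosis,
                subject_id=f"{spec.cohort_id}-{diagnosis.value}-{i:04d}",
            ))
    return Cohort(cohort_id=spec.cohort_id, subjects=subjects)


def reference_cohort(spec: CohortSpec) -> Cohort:
    """Deterministic cohort materializing a spec's group summaries exactly.

    Every subject carries its group's mean values; sex and APOE e4 counts
    are hit exactly (the first ``round(pct * n / 100)`` subjects of each
    group are male / carriers). No randomness is involved, so group and
    pooled summary statistics recomputed from this cohort reproduce the
    published counts, percentages and weighted means exactly — useful for
    checking derived quantities against a printed cohort table.
    """
    subjects: list[SubjectRecord] = []
    for diagnosis in (Diagnosis.NORMAL, Diagnosis.MCI_AD, Diagnosis.AD):
        group = spec.groups.get(diagnosis)
        if group is None or group.n == 0:
            continue
        n_male = int(round(group.pct_male * group.n / 100.0))
        n_apoe = int(round(group.pct_apoe4 * group.n / 100.0))
        c3_raw = float(np.exp(group.log_c3_mean) * spec.c3_assay_factor)
        for i in range(group.n):
            subjects.append(SubjectRecord(
                subject_id=f"{spec.cohort_id}-ref-{diagnosis.value}-{i:04d}",
                cohort_id=spec.cohort_id,
                diagnosis=diagnosis,
                age=group.age_mean,
                sex=Sex.MALE if i < n_male else Sex.FEMALE,
                education=group.education_mean,
                apoe4_carrier=i < n_apoe,
                abeta42=group.abeta42_mean,
                ttau=group.ttau_mean,
                ptau181=group.ptau181_mean,
                c3_raw=c3_raw,
                fh=group.fh_mean,
            ))
    return Cohort(cohort_id=spec.cohort_id, subjects=subjects)


# ---------------------------------------------------------------------------
# Paired-cohort scenarios
# ---------------------------------------------------------------------------

def _nullify(spec: CohortSpec) -> CohortSpec:
    """Make the AD group distributionally identical to MCI-AD (keep its n).

    Labels then carry no signal: any detected separation is overfitting.
    """
    mci = spec.groups[Diagnosis.MCI_AD]
    ad_n = spec.groups[Diagnosis.AD].n
    groups = dict(spec.groups)
    groups[Diagnosis.AD] = dataclasses.replace(mci, n=ad_n)
    constrained = tuple(sorted(
        set(spec.ratio_constrained_groups) | {Diagnosis.MCI_AD, Diagnosis.AD},
        key=lambda d: d.value,
    ))
    return dataclasses.replace(
        spec, groups=groups, ratio_constrained_groups=constrained
    )


def _pair_seeds(master_seed: int) -> tuple[int, int]:
    state = np.random.SeedSequence((int(master_seed), 0xA1)).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def generate_null_pair(
    train_base: CohortSpec | None = None,
    test_base: CohortSpec | None = None,
    master_seed: int = 0,
) -> tuple[Cohort, Cohort]:
    """Independent training/test cohorts with no stage signal.

    Both cohorts share their within-cohort distributions across the
    MCI-AD and AD groups; the two cohorts keep their distinct C3 assay
    factors, which per-cohort z-scoring must render invisible.
    """
    train_spec = _nullify(train_base or adni_cohort_spec())
    test_spec = _nullify(test_base or emory_cohort_spec())
    s1, s2 = _pair_seeds(master_seed)
    return generate_cohort(train_spec, s1), generate_cohort(test_spec, s2)


def generate_staged_pair(
    train_base: CohortSpec | None = None,
    test_base: CohortSpec | None = None,
    c3_shift: float = -1.0,
    fh_shift: float = -1.0,
    exec_slope_gap: float = 0.0,
    mem_slope_gap: float = 0.0,
    master_seed: int = 0,
) -> tuple[Cohort, Cohort]:
    """Training/test pair with stage signal confined to C3 and FH.

    Starting from the null configuration (AD distributionally identical
    to MCI-AD), the AD group's log-C3 and FH means are shifted by the
    given number of group SDs — negative shifts place lower complement
    levels in the more advanced stage — while every other feature stays
    identically distributed across stages, so only the experiment that
    includes C3/FH can separate the classes. Optional slope gaps make
    the AD group's cognitive decline steeper (Z/month); at zero shifts
    and gaps this reduces exactly to :func:`generate_null_pair`.
    """
    def _stage(spec: CohortSpec) -> CohortSpec:
        spec = _nullify(spec)
        ad = spec.groups[Diagnosis.AD]
        ad = dataclasses.replace(
            ad,
            log_c3_mean=ad.log_c3_mean + c3_shift * ad.log_c3_sd,
            fh_mean=ad.fh_mean + fh_shift * ad.fh_sd,
            exec_slope=ad.exec_slope - exec_slope_gap,
            mem_slope=ad.mem_slope - mem_slope_gap,
        )
        groups = dict(spec.groups)
        groups[Diagnosis.AD] = ad
        return dataclasses.replace(spec, groups=groups)

    train_spec = _stage(train_base or adni_cohort_spec())
    test_spec = _stage(test_base or emory_cohort_spec())
    s1, s2 = _pair_seeds(master_seed)
    return generate_cohort(train_spec, s1), generate_cohort(test_spec, s2)
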