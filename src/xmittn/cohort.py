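"""Cohort data model, tabular I/O, harmonization, and summaries.

A cohort is a list of per-subject records: demographics (age, sex,
education, APOE e4 carrier status), a clinical diagnosis, CSF analytes
(Abeta42, t-Tau, p-Tau181, complement C3, factor H), and optional
longitudinal cognitive visits. Mild cognitive impairment is attributed
to Alzheimer's disease (MCI-AD) when the CSF t-Tau/Abeta42 ratio is at
least 0.39; the :func:`apply_ad_filter` predicate implements that rule
with an inclusive boundary.

Because C3 immunoassays differ between centers, raw C3 is never compared
across cohorts. Instead :func:`normalize_c3` log-transforms C3 and
z-scores it against the cohort's own cognitively normal reference group,
which removes any cohort-level multiplicative assay factor.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateReferenceError,
    InsufficientReferenceError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default inclusive threshold on the CSF t-Tau/Abeta42 ratio that
#: classifies an MCI subject as MCI due to AD.
AD_RATIO_THRESHOLD = 0.39


class Diagnosis(str, Enum):
    NORMAL = "NORMAL"
    MCI_OTHER = "MCI_OTHER"
    MCI_AD = "MCI_AD"
    AD = "AD"


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class Experiment(str, Enum):
    """The two feature-set experiments.

    EXP1 uses demographics, APOE e4 status and the established CSF AD
    biomarkers; EXP2 adds z-scored log C3 and factor H.
    """

    EXP1 = "EXP1"
    EXP2 = "EXP2"


EXP1_FEATURES = ("age", "sex_male", "apoe4", "abeta42", "ttau", "ptau181")
EXP2_FEATURES = EXP1_FEATURES + ("c3_z", "fh")


@dataclass(frozen=True)
class LongitudinalVisit:
    """One follow-up visit: months from baseline plus cognitive Z scores.

    Either score may be missing (None).
    """

    months_from_baseline: float
    executive_z: float | None = None
    memory_z: float | None = None

    def __post_init__(self):
        if self.months_from_baseline < 0:
            raise ValidationError(
                f"months_from_baseline must be >= 0, got {self.months_from_baseline}"
            )


@dataclass
class SubjectRecord:
    subject_id: str
    cohort_id: str
    diagnosis: Diagnosis
    age: float
    sex: Sex
    apoe4_carrier: bool
    abeta42: float
    ttau: float
    ptau181: float
    c3_raw: float
    fh: float
    education: float | None = None
    c3_z: float | None = None
    visits: list[LongitudinalVisit] = field(default_factory=list)

    def __post_init__(self):
        self.diagnosis = Diagnosis(self.diagnosis)
        self.sex = Sex(self.sex)
        errors = []
        if not self.age > 0:
            errors.append(f"age must be > 0, got {self.age}")
        if self.education is not None and not self.education >= 0:
            errors.append(f"education must be >= 0, got {self.education}")
        for name in ("abeta42", "ttau", "ptau181", "c3_raw", "fh"):
            value = getattr(self, name)
            if not value > 0:
                errors.append(f"{name} must be > 0, got {value}")
        if errors:
            raise ValidationError(
                f"subject {self.subject_id!r}: " + "; ".join(errors), errors
            )
        if self.diagnosis is Diagnosis.MCI_AD and not apply_ad_filter(self):
            raise ValidationError(
                f"subject {self.subject_id!r}: diagnosis MCI_AD requires "
                f"ttau/abeta42 >= {AD_RATIO_THRESHOLD}, got "
                f"{self.ttau / self.abeta42:.4f}"
            )
        months = [v.months_from_baseline for v in self.visits]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValidationError(
                f"subject {self.subject_id!r}: visit months must be strictly increasing"
            )


@dataclass
class Cohort:
    """A set of subjects plus the cognitively normal reference group.

    ``normal_reference`` defaults to the NORMAL-diagnosis subjects of the
    cohort itself but may be a disjoint set (e.g. a separately recruited
    reference panel). ``metadata`` carries assay annotations such as
    lower limits of detection; it is never used in computation.
    """

    cohort_id: str
    subjects: list[SubjectRecord]
    normal_reference: list[SubjectRecord] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"cohort {self.cohort_id!r}: duplicate subject_id(s): {dupes}"
            )
        if self.normal_reference is None:
            self.normal_reference = [
                s for s in self.subjects if s.diagnosis is Diagnosis.NORMAL
            ]

    def __len__(self):
        return len(self.subjects)

    def by_diagnosis(self, *diagnoses: Diagnosis) -> list[SubjectRecord]:
        wanted = {Diagnosis(d) for d in diagnoses}
        return [s for s in self.subjects if s.diagnosis in wanted]


@dataclass
class FeatureMatrix:
    """Numeric design matrix for one experiment, rows in fixed order.

    Labels are 0 for MCI-AD and 1 for mild AD dementia.
    """

    experiment: Experiment
    feature_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        expected = EXP1_FEATURES if self.experiment is Experiment.EXP1 else EXP2_FEATURES
        if tuple(self.feature_names) != expected:
            raise ValidationError(
                f"feature_names for {self.experiment.value} must be {expected}"
            )
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValidationError("values shape inconsistent with rows/columns")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature matrix contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


# ---------------------------------------------------------------------------
# Harmonization rules
# ---------------------------------------------------------------------------

def apply_ad_filter(subject: SubjectRecord, threshold: float = AD_RATIO_THRESHOLD) -> bool:
    """True iff the subject's t-Tau/Abeta42 ratio is >= ``threshold``.

    The boundary is inclusive: a ratio of exactly 0.39 qualifies as
    MCI due to AD.
    """
    if subject.abeta42 is None or not subject.abeta42 > 0:
        raise ValidationError(
            f"subject {subject.subject_id!r}: undefined ratio (abeta42 missing or <= 0)"
        )
    if subject.ttau is None:
        raise ValidationError(f"subject {subject.subject_id!r}: ttau missing")
    return subject.ttau / subject.abeta42 >= threshold


def normalize_c3(cohort: Cohort) -> Cohort:
    """Return a copy of the cohort with ``c3_z`` populated on every subject.

    ``c3_z = (ln(c3_raw) - mean_ref) / sd_ref`` where the reference mean
    and sample SD (n-1 denominator) are computed over ln(c3_raw) of the
    cohort's own normal reference. Normalization is strictly per-cohort:
    never pool references across cohorts, because the assay factor to be
    removed is cohort-specific.
    """
    ref = cohort.normal_reference
    if ref is None or len(ref) < 2:
        raise InsufficientReferenceError(
            f"cohort {cohort.cohort_id!r}: need >= 2 normal-reference subjects, "
            f"got {0 if not ref else len(ref)}"
        )
    log_ref = np.log([s.c3_raw for s in ref])
    mean_ref = float(np.mean(log_ref))
    sd_ref = float(np.std(log_ref, ddof=1))
    if sd_ref == 0:
        raise DegenerateReferenceError(
            f"cohort {cohort.cohort_id!r}: reference log-C3 SD is zero"
        )

    def _with_z(subject: SubjectRecord) -> SubjectRecord:
        z = (math.log(subject.c3_raw) - mean_ref) / sd_ref
        return dataclasses.replace(subject, c3_z=z)

    subjects = [_with_z(s) for s in cohort.subjects]
    subject_ids = {s.subject_id for s in cohort.subjects}
    reference = [
        _with_z(s) if s.subject_id not in subject_ids
        else next(t for t in subjects if t.subject_id == s.subject_id)
        for s in ref
    ]
    return Cohort(
        cohort_id=cohort.cohort_id,
        subjects=subjects,
        normal_reference=reference,
        metadata=dict(cohort.metadata),
    )


def build_feature_matrix(cohort: Cohort, experiment: Experiment | str) -> FeatureMatrix:
    """Design matrix over the MCI-AD and AD subjects of a cohort.

    Subjects with any missing required feature are excluded (complete-case
    rule) and the exclusions logged. Labels: 0 = MCI-AD, 1 = AD.
    """
    experiment = Experiment(experiment)
    names = EXP1_FEATURES if experiment is Experiment.EXP1 else EXP2_FEATURES
    eligible = cohort.by_diagnosis(Diagnosis.MCI_AD, Diagnosis.AD)
    if experiment is Experiment.EXP2 and any(s.c3_z is None for s in eligible):
        raise ValidationError(
            "c3_z missing: apply normalize_c3 to the cohort before building "
            "an EXP2 feature matrix"
        )

    rows, labels, ids, excluded = [], [], [], []
    for s in eligible:
        row = [
            s.age,
            1.0 if s.sex is Sex.MALE else 0.0,
            1.0 if s.apoe4_carrier else 0.0,
            s.abeta42,
            s.ttau,
            s.ptau181,
        ]
        if experiment is Experiment.EXP2:
            row += [s.c3_z, s.fh]
        if not all(v is not None and np.isfinite(v) for v in row):
            excluded.append(s.subject_id)
            continue
        rows.append(row)
        labels.append(0 if s.diagnosis is Diagnosis.MCI_AD else 1)
        ids.append(s.subject_id)
    if excluded:
        logger.info(
            "build_feature_matrix(%s): excluded %d incomplete subject(s): %s",
            experiment.value, len(excluded), excluded,
        )
    if not rows:
        raise ValidationError(
            f"cohort {cohort.cohort_id!r}: no eligible MCI_AD/AD subjects with "
            f"complete features"
        )
    return FeatureMatrix(
        experiment=experiment,
        feature_names=names,
        values=np.array(rows, dtype=float),
        labels=np.array(labels, dtype=int),
        subject_ids=ids,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = (
    "subject_id", "diagnosis", "age", "sex", "education", "apoe4_carrier",
    "abeta42", "ttau", "ptau181", "c3_raw", "fh", "c3_z",
)
_REQUIRED_COLUMNS = tuple(c for c in _CANONICAL_COLUMNS if c not in ("education", "c3_z"))

_SEX_ALIASES = {
    "MALE": Sex.MALE, "M": Sex.MALE, "1": Sex.MALE,
    "FEMALE": Sex.FEMALE, "F": Sex.FEMALE, "0": Sex.FEMALE,
}
_BOOL_ALIASES = {
    "TRUE": True, "T": True, "1": True, "YES": True, "Y": True,
    "FALSE": False, "F": False, "0": False, "NO": False, "N": False,
}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().upper()
    if key in _BOOL_ALIASES:
        return _BOOL_ALIASES[key]
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    visits_path: str | Path | None = None,
    cohort_id: str | None = None,
) -> Cohort:
    """Read a cohort from a CSV/TSV file, one row per subject.

    Parameters
    ----------
    path:
        Delimited text file with a header row. ``.tsv`` extension selects
        tab delimiting, anything else comma.
    schema:
        Optional mapping from canonical column names (``subject_id``,
        ``diagnosis``, ``age``, ``sex``, ``education``, ``apoe4_carrier``,
        ``abeta42``, ``ttau``, ``ptau181``, ``c3_raw``, ``fh``) to the
        column names actually present in the file.
    visits_path:
        Optional long-format visits file with columns ``subject_id``,
        ``months_from_baseline``, ``executive_z``, ``memory_z``.
    cohort_id:
        Defaults to the file stem.

    Rows failing type or range checks are collected and reported together
    with their (1-based, header-exclusive) row numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in _CANONICAL_COLUMNS if schema.get(c, c) in frame.columns}
    frame = frame.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")

    visits_by_subject: dict[str, list[LongitudinalVisit]] = {}
    if visits_path is not None:
        visits_by_subject = _read_visits(visits_path)

    cohort_id = cohort_id or path.stem
    subjects, row_errors = [], []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        record = row._asdict()
        try:
            subject = SubjectRecord(
                subject_id=str(record["subject_id"]),
                cohort_id=cohort_id,
                diagnosis=Diagnosis(str(record["diagnosis"]).strip().upper()),
                age=float(record["age"]),
                sex=_SEX_ALIASES[str(record["sex"]).strip().upper()],
                education=_optional_float(record.get("education")),
                apoe4_carrier=_parse_bool(record["apoe4_carrier"]),
                abeta42=float(record["abeta42"]),
                ttau=float(record["ttau"]),
                ptau181=float(record["ptau181"]),
                c3_raw=float(record["c3_raw"]),
                fh=float(record["fh"]),
                c3_z=_optional_float(record.get("c3_z")),
                visits=visits_by_subject.get(str(record["subject_id"]), []),
            )
        except (ValidationError, ValueError, KeyError) as exc:
            row_errors.append(f"row {i}: {exc}")
            continue
        subjects.append(subject)
    if row_errors:
        raise ValidationError(
            f"{path.name}: {len(row_errors)} invalid row(s):\n  " + "\n  ".join(row_errors),
            row_errors,
        )
    return Cohort(cohort_id=cohort_id, subjects=subjects)


def _read_visits(path: str | Path) -> dict[str, list[LongitudinalVisit]]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    required = {"subject_id", "months_from_baseline"}
    if not required.issubset(frame.columns):
        raise SchemaError(f"{path.name}: visits file needs columns {sorted(required)}")
    out: dict[str, list[LongitudinalVisit]] = {}
    for sid, group in frame.groupby("subject_id", sort=False):
        group = group.sort_values("months_from_baseline")
        out[str(sid)] = [
            LongitudinalVisit(
                months_from_baseline=float(r.months_from_baseline),
                executive_z=_optional_float(getattr(r, "executive_z", None)),
                memory_z=_optional_float(getattr(r, "memory_z", None)),
            )
            for r in group.itertuples(index=False)
        ]
    return out


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    visits_path: str | Path | None = None,
) -> None:
    """Write a cohort as a canonical-column CSV (visits in a companion file).

    ``read_cohort(write_cohort(c))`` is the identity on all typed fields.
    Visits, when present and ``visits_path`` is given, go to a long-format
    CSV keyed by ``subject_id``.
    """
    path = Path(path)
    rows = []
    for s in cohort.subjects:
        rows.append({
            "subject_id": s.subject_id,
            "diagnosis": s.diagnosis.value,
            "age": repr(s.age),
            "sex": s.sex.value,
            "education": "" if s.education is None else repr(s.education),
            "apoe4_carrier": str(s.apoe4_carrier),
            "abeta42": repr(s.abeta42),
            "ttau": repr(s.ttau),
            "ptau181": repr(s.ptau181),
            "c3_raw": repr(s.c3_raw),
            "fh": repr(s.fh),
            "c3_z": "" if s.c3_z is None else repr(s.c3_z),
        })
    frame = pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS))
    frame.to_csv(path, index=False)
    if visits_path is not None:
        vrows = []
        for s in cohort.subjects:
            for v in s.visits:
                vrows.append({
                    "subject_id": s.subject_id,
                    "months_from_baseline": repr(v.months_from_baseline),
                    "executive_z": "" if v.executive_z is None else repr(v.executive_z),
                    "memory_z": "" if v.memory_z is None else repr(v.memory_z),
                })
        pd.DataFrame(
            vrows,
            columns=["subject_id", "months_from_baseline", "executive_z", "memory_z"],
        ).to_csv(visits_path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_cohort(
    cohort: Cohort,
    groups: Sequence[Diagnosis | str] | None = None,
) -> pd.DataFrame:
    """Per-diagnosis-group demographic/biomarker summary plus a pooled row.

    For each group: n, male count and percentage, APOE e4 carrier count
    and percentage, mean/SD of age, education, each CSF analyte, and
    z-scored log C3 when populated. Percentages are 100 x count / n. The
    ``POOLED`` row pools subjects across the requested groups, so its
    means are the sample-size-weighted means and its percentages derive
    from pooled counts. Empty groups yield n=0 with null statistics;
    single-subject groups have null SDs.
    """
    if groups is None:
        groups = [Diagnosis.MCI_AD, Diagnosis.AD]
    groups = [Diagnosis(g) for g in groups]
    if not groups:
        raise ValidationError("groups must be non-empty")

    def _stats(subjects: list[SubjectRecord]) -> dict:
        n = len(subjects)
        out = {"n": n}
        if n == 0:
            for key in ("male_n", "female_n", "apoe4_n"):
                out[key] = 0
            for key in ("male_pct", "female_pct", "apoe4_pct"):
                out[key] = np.nan
        else:
            male = sum(s.sex is Sex.MALE for s in subjects)
            apoe = sum(s.apoe4_carrier for s in subjects)
            out.update(
                male_n=male, male_pct=100.0 * male / n,
                female_n=n - male, female_pct=100.0 * (n - male) / n,
                apoe4_n=apoe, apoe4_pct=100.0 * apoe / n,
            )
        fields = {
            "age": [s.age for s in subjects],
            "education": [s.education for s in subjects if s.education is not None],
            "abeta42": [s.abeta42 for s in subjects],
            "ttau": [s.ttau for s in subjects],
            "ptau181": [s.ptau181 for s in subjects],
            "fh": [s.fh for s in subjects],
            "c3_z": [s.c3_z for s in subjects if s.c3_z is not None],
        }
        for name, values in fields.items():
            arr = np.asarray(values, dtype=float)
            out[f"{name}_mean"] = float(np.mean(arr)) if arr.size else np.nan
            out[f"{name}_sd"] = float(np.std(arr, ddof=1)) if arr.size > 1 else np.nan
        return out

    table = {}
    pooled: list[SubjectRecord] = []
    for g in groups:
        members = cohort.by_diagnosis(g)
        pooled.extend(members)
        table[g.value] = _stats(members)
    table["POOLED"] = _stats(pooled)
    return pd.DataFrame(table).T


def summary_to_json(summary: pd.DataFrame) -> str:
    """Serialize a cohort summary (NaN rendered as null)."""
    payload = {
        group: {k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in row.items()}
        for group, row in summary.to_dict(orient="index").items()
    }
    return json.dumps(payload, indent=2)
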