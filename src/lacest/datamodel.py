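"""Record types for subjects and constant-work-rate (CWR) tests, with CSV I/O.

A study cohort is represented as a :class:`Dataset`: one row per subject
(anthropometrics and resting heart rate) plus up to three CWR test records
per subject, one for each intensity regime (LC = low, MC = moderate,
HC = high constant load). End-exercise physiologic variables and the
measured venous blood lactate live on the test record; lactate may be
absent so that trained models can score unlabeled tests.

Files are plain UTF-8 CSV with a fixed header, "." decimal point and a
deterministic row order, so that writing the same dataset twice produces
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import LinkageError, SchemaError, ValidationError

__all__ = [
    "Sex",
    "Intensity",
    "INTENSITY_PROTOCOL",
    "SubjectRecord",
    "CWRTestRecord",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "SUBJECTS_HEADER",
    "TESTS_HEADER",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Intensity(str, Enum):
    """CWR intensity regime relative to the ventilatory thresholds."""

    LC = "LC"  # low constant load, below VT1
    MC = "MC"  # moderate constant load, between VT1 and VT2
    HC = "HC"  # high constant load, above VT2


#: protocol defaults: fraction of peak work rate and duration (minutes)
INTENSITY_PROTOCOL: dict[Intensity, tuple[float, float]] = {
    Intensity.LC: (0.35, 15.0),
    Intensity.MC: (0.60, 10.0),
    Intensity.HC: (0.90, 4.0),
}

_INTENSITY_ORDER = {Intensity.LC: 0, Intensity.MC: 1, Intensity.HC: 2}

SUBJECTS_HEADER = [
    "subject_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "bmi",
    "resting_hr",
]
TESTS_HEADER = [
    "subject_id",
    "intensity",
    "percent_peak_wr",
    "work_rate_w",
    "duration_min",
    "ex_hr",
    "bf",
    "vt_l",
    "lactate_mmol_l",
]

#: hard plausibility bounds for subject fields
_SUBJECT_BOUNDS = {
    "age": (10.0, 100.0),
    "height_cm": (100.0, 230.0),
    "weight_kg": (25.0, 250.0),
    "resting_hr": (30.0, 120.0),
}
_BMI_TOL = 0.5


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's anthropometrics and resting heart rate.

    BMI is stored *and* cross-checked against weight/height (rather than
    recomputed) because it is treated as a primary measurement.
    """

    subject_id: str
    age: float
    sex: Sex
    height_cm: float
    weight_kg: float
    bmi: float
    resting_hr: float

    def validate(self, context: str = "") -> None:
        where = f"{context}subject {self.subject_id!r}"
        if not self.subject_id:
            raise ValidationError(f"{where}: subject_id must be non-empty")
        for name, (lo, hi) in _SUBJECT_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"{where}: {name} = {v} violates {lo} <= {name} <= {hi}"
                )
        expected = self.weight_kg / (self.height_cm / 100.0) ** 2
        if abs(self.bmi - expected) > _BMI_TOL:
            raise ValidationError(
                f"{where}: bmi = {self.bmi} inconsistent with "
                f"weight/height^2 = {expected:.2f} (tolerance {_BMI_TOL})"
            )


@dataclass(frozen=True)
class CWRTestRecord:
    """End-exercise variables of one constant-work-rate test.

    ``lactate_mmol_l`` is the measured venous blood lactate; ``None`` marks
    a prediction-only record (empty cell in the CSV).
    """

    subject_id: str
    intensity: Intensity
    percent_peak_wr: float
    work_rate_w: float
    duration_min: float
    ex_hr: float
    bf: float
    vt_l: float
    lactate_mmol_l: float | None = None

    def validate(self, context: str = "") -> None:
        where = f"{context}test ({self.subject_id!r}, {self.intensity.value})"
        if self.lactate_mmol_l is not None and self.lactate_mmol_l < 0:
            raise ValidationError(f"{where}: lactate >= 0 violated "
                                  f"(got {self.lactate_mmol_l})")
        if not self.vt_l > 0:
            raise ValidationError(f"{where}: vt > 0 violated (got {self.vt_l})")
        if not self.bf > 0:
            raise ValidationError(f"{where}: bf > 0 violated (got {self.bf})")
        for name in ("percent_peak_wr", "work_rate_w", "duration_min", "ex_hr"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{where}: {name} must be positive and finite (got {v})"
                )


@dataclass
class Dataset:
    """A cohort: subjects plus their CWR test records.

    Invariants (checked by :meth:`validate`): every test's ``subject_id``
    resolves to exactly one subject; at most one test per
    (subject, intensity) pair; end-exercise HR is at least the linked
    subject's resting HR.
    """

    subjects: list[SubjectRecord] = field(default_factory=list)
    tests: list[CWRTestRecord] = field(default_factory=list)

    @property
    def subject_map(self) -> dict[str, SubjectRecord]:
        return {s.subject_id: s for s in self.subjects}

    def validate(self) -> None:
        ids: dict[str, int] = {}
        for i, s in enumerate(self.subjects):
            s.validate(context=f"subjects row {i}: ")
            if s.subject_id in ids:
                raise ValidationError(
                    f"subjects row {i}: duplicate subject_id {s.subject_id!r}"
                )
            ids[s.subject_id] = i
        seen: set[tuple[str, Intensity]] = set()
        smap = self.subject_map
        for i, t in enumerate(self.tests):
            t.validate(context=f"tests row {i}: ")
            if t.subject_id not in smap:
                raise LinkageError(
                    f"tests row {i}: subject_id {t.subject_id!r} does not "
                    "resolve to a subject"
                )
            key = (t.subject_id, t.intensity)
            if key in seen:
                raise ValidationError(
                    f"tests row {i}: more than one test for "
                    f"({t.subject_id!r}, {t.intensity.value})"
                )
            seen.add(key)
            rhr = smap[t.subject_id].resting_hr
            if t.ex_hr < rhr:
                raise ValidationError(
                    f"tests row {i}: ex_hr = {t.ex_hr} < resting_hr = {rhr} "
                    "of the linked subject"
                )

    def subset_tests(self, indices: Sequence[int]) -> "Dataset":
        """New Dataset containing the selected test rows (subjects kept)."""
        return Dataset(subjects=list(self.subjects),
                       tests=[self.tests[i] for i in indices])

    def lactate_vector(self) -> list[float]:
        """Measured lactate for every test; raises if any is missing."""
        out = []
        for i, t in enumerate(self.tests):
            if t.lactate_mmol_l is None:
                raise ValidationError(
                    f"tests row {i}: lactate is missing but required here"
                )
            out.append(t.lactate_mmol_l)
        return out


def _require_columns(df: pd.DataFrame, header: Iterable[str], path) -> None:
    missing = [c for c in header if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _as_float(value, where: str, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: {column} = {value!r} is not numeric")


def read_dataset(subjects_path, tests_path) -> Dataset:
    """Read and validate a cohort from the two-file CSV layout.

    Raises :class:`SchemaError` for missing columns, :class:`ValidationError`
    for invariant violations (message names the row and rule) and
    :class:`LinkageError` for unresolvable subject ids.
    """
    sdf = pd.read_csv(subjects_path, dtype=str, keep_default_na=False)
    tdf = pd.read_csv(tests_path, dtype=str, keep_default_na=False)
    _require_columns(sdf, SUBJECTS_HEADER, subjects_path)
    _require_columns(tdf, TESTS_HEADER, tests_path)

    subjects = []
    for i, row in enumerate(sdf.itertuples(index=False)):
        where = f"subjects row {i}"
        sex_raw = getattr(row, "sex")
        try:
            sex = Sex(sex_raw)
        except ValueError:
            raise ValidationError(
                f"{where}: sex must be 'male' or 'female' (got {sex_raw!r})"
            )
        subjects.append(SubjectRecord(
            subject_id=getattr(row, "subject_id"),
            age=_as_float(getattr(row, "age"), where, "age"),
            sex=sex,
            height_cm=_as_float(getattr(row, "height_cm"), where, "height_cm"),
            weight_kg=_as_float(getattr(row, "weight_kg"), where, "weight_kg"),
            bmi=_as_float(getattr(row, "bmi"), where, "bmi"),
            resting_hr=_as_float(getattr(row, "resting_hr"), where, "resting_hr"),
        ))

    tests = []
    for i, row in enumerate(tdf.itertuples(index=False)):
        where = f"tests row {i}"
        intensity_raw = getattr(row, "intensity")
        try:
            intensity = Intensity(intensity_raw)
        except ValueError:
            raise ValidationError(
                f"{where}: intensity must be one of LC/MC/HC "
                f"(got {intensity_raw!r})"
            )
        lac_raw = getattr(row, "lactate_mmol_l")
        lactate = None if lac_raw == "" else _as_float(lac_raw, where,
                                                       "lactate_mmol_l")
        tests.append(CWRTestRecord(
            subject_id=getattr(row, "subject_id"),
            intensity=intensity,
            percent_peak_wr=_as_float(getattr(row, "percent_peak_wr"),
                                      where, "percent_peak_wr"),
            work_rate_w=_as_float(getattr(row, "work_rate_w"), where,
                                  "work_rate_w"),
            duration_min=_as_float(getattr(row, "duration_min"), where,
                                   "duration_min"),
            ex_hr=_as_float(getattr(row, "ex_hr"), where, "ex_hr"),
            bf=_as_float(getattr(row, "bf"), where, "bf"),
            vt_l=_as_float(getattr(row, "vt_l"), where, "vt_l"),
            lactate_mmol_l=lactate,
        ))

    ds = Dataset(subjects=subjects, tests=tests)
    ds.validate()
    return ds


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        # repr round-trips exactly, keeping read(write(ds)) the identity
        return repr(value)
    return str(value)


def write_dataset(ds: Dataset, subjects_path, tests_path) -> None:
    """Write a cohort as two CSV files with deterministic order and format.

    Subjects are sorted by id; tests by (subject id, LC < MC < HC). Floats
    are written with shortest round-trip representation, so the same
    Dataset always produces byte-identical files.
    """
    ds.validate()
    subjects = sorted(ds.subjects, key=lambda s: s.subject_id)
    tests = sorted(ds.tests,
                   key=lambda t: (t.subject_id, _INTENSITY_ORDER[t.intensity]))

    with open(subjects_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(SUBJECTS_HEADER) + "\n")
        for s in subjects:
            fh.write(",".join([
                s.subject_id, _fmt(s.age), s.sex.value, _fmt(s.height_cm),
                _fmt(s.weight_kg), _fmt(s.bmi), _fmt(s.resting_hr),
            ]) + "\n")

    with open(tests_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TESTS_HEADER) + "\n")
        for t in tests:
            fh.write(",".join([
                t.subject_id, t.intensity.value, _fmt(t.percent_peak_wr),
                _fmt(t.work_rate_w), _fmt(t.duration_min), _fmt(t.ex_hr),
                _fmt(t.bf), _fmt(t.vt_l), _fmt(t.lactate_mmol_l),
            ]) + "\n")
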