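"""Subject-level data model for matched case-control studies.

A study record carries the matching identifier, case/control status, the
matching variables (sex, age) and the anthropometric measurements from which
body-mass index (BMI) and waist-to-hip ratio (WHR) are derived:

    BMI = weight [kg] / (height [m])^2
    WHR = waist circumference / hip circumference

BMI is categorized by the Chinese adult standard (low < 18.5, normal
18.5-24.0, overweight 24.0-28.0, obese >= 28.0 kg/m^2; half-open intervals so
the categories partition the positive axis), and WHR abnormality uses the
sex-specific cutoffs > 0.90 (male) and > 0.80 (female).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "Status",
    "Sex",
    "BMICategory",
    "SubjectRecord",
    "StudyDataset",
    "compute_bmi",
    "categorize_bmi",
    "classify_whr",
    "load_dataset",
    "BMI_LOW_CUTOFF",
    "BMI_OVERWEIGHT_CUTOFF",
    "BMI_OBESE_CUTOFF",
    "WHR_CUTOFFS",
    "DEFAULT_COLUMNS",
    "MAX_PAIR_AGE_GAP",
]

BMI_LOW_CUTOFF = 18.5
BMI_OVERWEIGHT_CUTOFF = 24.0
BMI_OBESE_CUTOFF = 28.0
#: sex-specific WHR abnormality thresholds (abnormal iff strictly above)
WHR_CUTOFFS = {"male": 0.90, "female": 0.80}
#: maximum within-pair age difference allowed by the matching criteria
MAX_PAIR_AGE_GAP = 5.0


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class BMICategory(str, enum.Enum):
    LOW = "low"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"

    @property
    def abnormal(self) -> bool:
        """Abnormal weight pools low, overweight and obese against normal."""
        return self is not BMICategory.NORMAL


def compute_bmi(weight: float, height: float) -> float:
    """Body-mass index in kg/m^2 from weight in kg and height in cm."""
    if not weight > 0:
        raise ValidationError(f"weight must be positive, got {weight!r}")
    if not height > 0:
        raise ValidationError(f"height must be positive, got {height!r}")
    return weight / (height / 100.0) ** 2


def categorize_bmi(bmi: float) -> BMICategory:
    """Categorize BMI with half-open intervals [18.5, 24), [24, 28), [28, inf)."""
    if not bmi > 0:
        raise ValidationError(f"bmi must be positive, got {bmi!r}")
    if bmi < BMI_LOW_CUTOFF:
        return BMICategory.LOW
    if bmi < BMI_OVERWEIGHT_CUTOFF:
        return BMICategory.NORMAL
    if bmi < BMI_OBESE_CUTOFF:
        return BMICategory.OVERWEIGHT
    return BMICategory.OBESE


def classify_whr(whr: float, sex: Sex | str) -> bool:
    """True iff the waist-to-hip ratio is abnormal for the given sex
    (> 0.90 male, > 0.80 female; the cutoff value itself is normal)."""
    if not whr > 0:
        raise ValidationError(f"whr must be positive, got {whr!r}")
    sex = Sex(sex)
    return whr > WHR_CUTOFFS[sex.value]


@dataclass
class SubjectRecord:
    """One study participant with derived anthropometric indices."""

    subject_id: str
    pair_id: str
    status: Status
    sex: Sex
    age: float
    height: float  # cm
    weight: float  # kg
    waist: float  # cm
    hip: float  # cm
    family_history: bool
    bmi: float = field(init=False)
    bmi_category: BMICategory = field(init=False)
    whr: float = field(init=False)
    whr_abnormal: bool = field(init=False)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.status = Status(self.status)
        self.sex = Sex(self.sex)
        for name in ("age", "height", "weight", "waist", "hip"):
            value = float(getattr(self, name))
            if not value > 0:
                raise ValidationError(f"{name} must be positive, got {value!r}")
            setattr(self, name, value)
        if not self.age < 130:
            raise ValidationError(f"age must be below 130 years, got {self.age!r}")
        self.family_history = bool(self.family_history)
        self.bmi = compute_bmi(self.weight, self.height)
        self.bmi_category = categorize_bmi(self.bmi)
        self.whr = self.waist / self.hip
        self.whr_abnormal = classify_whr(self.whr, self.sex)

    @property
    def is_case(self) -> bool:
        return self.status is Status.CASE

    @property
    def bmi_abnormal(self) -> bool:
        return self.bmi_category.abnormal

    def exposure_cell(self) -> tuple[int, int]:
        """(family-history, BMI-abnormal) joint-exposure indicator pair."""
        return (int(self.family_history), int(self.bmi_abnormal))


#: default CSV column names; override via the ``columns`` mapping
DEFAULT_COLUMNS = {
    "subject_id": "subject_id",
    "pair_id": "pair_id",
    "status": "status",
    "sex": "sex",
    "age": "age",
    "height": "height_cm",
    "weight": "weight_kg",
    "waist": "waist_cm",
    "hip": "hip_cm",
    "family_history": "family_history",
}

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}
_STATUS_ALIASES = {"case": Status.CASE, "1": Status.CASE,
                   "control": Status.CONTROL, "0": Status.CONTROL}
_SEX_ALIASES = {"male": Sex.MALE, "m": Sex.MALE,
                "female": Sex.FEMALE, "f": Sex.FEMALE}


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean flag")


@dataclass
class StudyDataset:
    """A validated collection of subject records.

    ``records`` are all rows that passed field validation. Pair-based
    analyses additionally require complete pairs (one case, one control per
    pair id); incomplete pairs stay in ``records`` for unconditional use but
    are listed in ``incomplete_pairs``. ``dropped`` logs rows rejected at
    load time with the reason.
    """

    records: list[SubjectRecord]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    pair_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._pairs = self._index_pairs()

    def _index_pairs(self) -> dict[str, tuple[SubjectRecord, SubjectRecord]]:
        by_pair: dict[str, list[SubjectRecord]] = {}
        for rec in self.records:
            by_pair.setdefault(rec.pair_id, []).append(rec)
        pairs: dict[str, tuple[SubjectRecord, SubjectRecord]] = {}
        self.incomplete_pairs: dict[str, str] = {}
        for pid, members in by_pair.items():
            cases = [r for r in members if r.is_case]
            controls = [r for r in members if not r.is_case]
            if len(cases) == 1 and len(controls) == 1:
                pairs[pid] = (cases[0], controls[0])
            else:
                self.incomplete_pairs[pid] = (
                    f"{len(cases)} case(s) and {len(controls)} control(s)"
                )
        return pairs

    @property
    def n_pairs(self) -> int:
        return len(self._pairs)

    @property
    def n_excluded_from_pairs(self) -> int:
        """Records whose pair is incomplete, excluded from pair analyses."""
        return sum(
            1 for rec in self.records if rec.pair_id in self.incomplete_pairs
        )

    def complete_pairs(self) -> dict[str, tuple[SubjectRecord, SubjectRecord]]:
        """Map pair id -> (case, control) over complete pairs only."""
        return dict(self._pairs)

    def paired_records(self) -> list[SubjectRecord]:
        """Records belonging to complete pairs, case before control."""
        out: list[SubjectRecord] = []
        for case, control in self._pairs.values():
            out.extend((case, control))
        return out

    def validate_pairs(self, strict: bool = False) -> list[str]:
        """Check the matching criteria (same sex, age gap <= 5 years).

        Violations are returned (and stored in ``pair_warnings``); with
        ``strict`` they raise :class:`ValidationError` instead.
        """
        problems = []
        for pid, (case, control) in self._pairs.items():
            if case.sex is not control.sex:
                problems.append(f"pair {pid}: case and control differ in sex")
            if abs(case.age - control.age) > MAX_PAIR_AGE_GAP:
                problems.append(
                    f"pair {pid}: age gap {abs(case.age - control.age):.1f}"
                    f" years exceeds {MAX_PAIR_AGE_GAP:.0f}"
                )
        self.pair_warnings = problems
        if strict and problems:
            raise ValidationError("; ".join(problems))
        return problems

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with derived columns appended."""
        rows = []
        for rec in self.records:
            row = {
                "subject_id": rec.subject_id,
                "pair_id": rec.pair_id,
                "status": rec.status.value,
                "sex": rec.sex.value,
                "age": rec.age,
                "height_cm": rec.height,
                "weight_kg": rec.weight,
                "waist_cm": rec.waist,
                "hip_cm": rec.hip,
                "family_history": int(rec.family_history),
                "bmi": rec.bmi,
                "bmi_category": rec.bmi_category.value,
                "whr": rec.whr,
                "whr_abnormal": int(rec.whr_abnormal),
            }
            row.update(rec.extras)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_dataset(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    extra_columns: Iterable[str] | None = None,
    strict: bool = False,
) -> StudyDataset:
    """Read a subject-level CSV into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV file with a header row; UTF-8, comma-separated.
    columns
        Mapping from canonical field names (keys of ``DEFAULT_COLUMNS``) to
        the column names used in the file. Unspecified fields keep defaults.
    extra_columns
        Columns to carry through untouched in ``SubjectRecord.extras``;
        by default every unrecognized column is carried through.
    strict
        Raise on pair-matching violations instead of recording warnings.

    Rows failing field validation are dropped and logged with the reason.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"cannot parse CSV {path}: {exc}") from exc
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(DEFAULT_COLUMNS)
        if unknown:
            raise SchemaError(f"unknown canonical field(s) in column map: {sorted(unknown)}")
        colmap.update(columns)
    missing = [c for c in colmap.values() if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    derived = {"bmi", "bmi_category", "whr", "whr_abnormal"}
    if extra_columns is None:
        # derived columns are recomputed on load, never carried as extras
        extra_columns = [
            c for c in frame.columns
            if c not in set(colmap.values()) and c not in derived
        ]
    records: list[SubjectRecord] = []
    dropped: list[tuple[str, str]] = []
    for idx, row in frame.iterrows():
        label = str(row[colmap["subject_id"]]) or f"row {idx}"
        try:
            status = _STATUS_ALIASES.get(str(row[colmap["status"]]).strip().lower())
            if status is None:
                raise ValidationError(
                    f"status must be case/control, got {row[colmap['status']]!r}")
            sex = _SEX_ALIASES.get(str(row[colmap["sex"]]).strip().lower())
            if sex is None:
                raise ValidationError(
                    f"sex must be male/female, got {row[colmap['sex']]!r}")
            numeric = {}
            for name in ("age", "height", "weight", "waist", "hip"):
                raw = row[colmap[name]]
                try:
                    numeric[name] = float(raw)
                except ValueError:
                    raise ValidationError(f"unparseable {name}: {raw!r}") from None
            rec = SubjectRecord(
                subject_id=label,
                pair_id=str(row[colmap["pair_id"]]),
                status=status,
                sex=sex,
                family_history=_parse_bool(row[colmap["family_history"]]),
                **numeric,
                extras={c: row[c] for c in extra_columns},
            )
        except ValidationError as exc:
            dropped.append((label, str(exc)))
            continue
        records.append(rec)
    dataset = StudyDataset(records=records, dropped=dropped)
    dataset.validate_pairs(strict=strict)
    return dataset
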