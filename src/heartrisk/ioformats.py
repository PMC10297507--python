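"""Record schema and I/O for the UCI heart-disease comma-separated dialect.

The pipeline's unit of data is a :class:`PatientRecord`: the 13 clinical
attributes (age, sex, chest-pain type, resting blood pressure, serum
cholesterol, fasting blood sugar flag, resting ECG code, maximum heart
rate, exercise-induced angina flag, ST depression, ST slope, fluoroscopy
vessel count, thalassemia code) plus an optional disease-stage target in
0..4.  Files use the UCI dialect: comma separated, optional header, the
literal ``?`` for a missing value.

Two validation modes exist because published samples of this data
routinely contain values outside the documented ranges (for example
``thal`` codes other than 3/6/7).  ``lenient`` (the default) keeps
out-of-range values and flags them as warnings; ``strict`` raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .exceptions import FormatError, ValidationError

__all__ = [
    "ATTRIBUTES",
    "SCHEMA",
    "AttributeSchema",
    "PatientRecord",
    "ValidationIssue",
    "binarize_target",
    "deduplicate",
    "read_records",
    "sample_records_path",
    "write_records",
]

MISSING_TOKEN = "?"


@dataclass(frozen=True)
class AttributeSchema:
    """Range/level constraints for one clinical attribute.

    ``kind`` is ``"numeric"`` (closed interval ``lo``..``hi``) or
    ``"categorical"`` (enumerated ``levels``).
    """

    name: str
    kind: Literal["numeric", "categorical"]
    description: str
    lo: float | None = None
    hi: float | None = None
    levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "numeric":
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValidationError(f"{self.name}: numeric interval must be nonempty")
        elif not self.levels:
            raise ValidationError(f"{self.name}: categorical level set must be nonempty")

    def in_range(self, value: float) -> bool:
        if self.kind == "numeric":
            return self.lo <= value <= self.hi  # type: ignore[operator]
        return value in self.levels


#: The 13 attributes, in file column order.
SCHEMA: tuple[AttributeSchema, ...] = (
    AttributeSchema("age", "numeric", "Patient age in years", 29, 77),
    AttributeSchema("sex", "categorical", "1 = male, 0 = female", levels=(0, 1)),
    AttributeSchema(
        "cp",
        "categorical",
        "Chest pain type: 1 angina, 2 atypical angina, 3 non-anginal, 4 asymptomatic",
        levels=(1, 2, 3, 4),
    ),
    AttributeSchema("trestbps", "numeric", "Resting blood pressure (mm Hg)", 94, 200),
    AttributeSchema("chol", "numeric", "Serum cholesterol (mg/dL)", 126, 564),
    AttributeSchema("fbs", "categorical", "Fasting blood sugar > 120 mg/dL", levels=(0, 1)),
    AttributeSchema(
        "restecg",
        "categorical",
        "Resting ECG: 0 normal, 1 ST-T abnormality, 2 definite ventricular hypertrophy",
        levels=(0, 1, 2),
    ),
    AttributeSchema("thalach", "numeric", "Maximum heart rate achieved (bpm)", 71, 202),
    AttributeSchema("exang", "categorical", "Exercise-induced angina", levels=(0, 1)),
    AttributeSchema("oldpeak", "numeric", "Exercise-induced ST depression", 0.0, 62.0),
    AttributeSchema(
        "slope", "categorical", "Peak-exercise ST slope: 1 up, 2 flat, 3 down", levels=(1, 2, 3)
    ),
    AttributeSchema("ca", "numeric", "Major vessels coloured by fluoroscopy", 0, 3),
    AttributeSchema(
        "thal",
        "categorical",
        "Thalassemia: 3 normal, 6 fixed defect, 7 reversible defect",
        levels=(3, 6, 7),
    ),
)

ATTRIBUTES: tuple[str, ...] = tuple(s.name for s in SCHEMA)
SCHEMA_BY_NAME: dict[str, AttributeSchema] = {s.name: s for s in SCHEMA}
TARGET_COLUMN = "target"
#: Column names the UCI processed files use for the disease stage.
_TARGET_ALIASES = frozenset({"target", "num", "goal"})


@dataclass
class PatientRecord:
    """One row of the record schema; ``None`` marks a missing value."""

    age: float | None = None
    sex: float | None = None
    cp: float | None = None
    trestbps: float | None = None
    chol: float | None = None
    fbs: float | None = None
    restecg: float | None = None
    thalach: float | None = None
    exang: float | None = None
    oldpeak: float | None = None
    slope: float | None = None
    ca: float | None = None
    thal: float | None = None
    raw_target: int | None = None
    uid: int = 0

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def values(self) -> tuple[float | None, ...]:
        """Attribute values in schema order (without target/uid)."""
        return tuple(getattr(self, a) for a in ATTRIBUTES)

    def row_key(self) -> tuple:
        """All 14 data fields — the identity used for deduplication."""
        return self.values() + (self.raw_target,)


@dataclass(frozen=True)
class ValidationIssue:
    uid: int
    attribute: str
    observed: object
    constraint: str
    severity: Literal["error", "warning"]


def _parse_value(token: str, line_no: int, col: str) -> float | None:
    token = token.strip()
    if token == MISSING_TOKEN or token == "":
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"line {line_no}: non-numeric value {token!r} in column {col}") from exc


def _format_value(value: float | None) -> str:
    if value is None:
        return MISSING_TOKEN
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def validate_record(record: PatientRecord) -> list[ValidationIssue]:
    """Schema issues for one record: missing → warning, out-of-range → error."""
    issues: list[ValidationIssue] = []
    for schema in SCHEMA:
        value = record.get(schema.name)
        if value is None:
            issues.append(
                ValidationIssue(record.uid, schema.name, None, "value missing", "warning")
            )
        elif not schema.in_range(value):
            constraint = (
                f"outside [{schema.lo}, {schema.hi}]"
                if schema.kind == "numeric"
                else f"not in levels {schema.levels}"
            )
            issues.append(ValidationIssue(record.uid, schema.name, value, constraint, "error"))
    if record.raw_target is not None and record.raw_target not in range(5):
        issues.append(
            ValidationIssue(record.uid, TARGET_COLUMN, record.raw_target, "stage not in 0..4", "error")
        )
    return issues


def _looks_like_header(tokens: Sequence[str]) -> bool:
    # a header names schema columns; a data row with a stray word is not one
    known = set(ATTRIBUTES) | _TARGET_ALIASES | {"thalac"}  # published misspelling
    named = sum(1 for tok in tokens if tok.strip().lower() in known)
    return named >= 2


def read_records(
    path: str | Path, mode: Literal["strict", "lenient"] = "lenient"
) -> tuple[list[PatientRecord], list[ValidationIssue]]:
    """Read a UCI-dialect record file.

    Accepts 13 columns (attributes only) or 14 (attributes + disease
    stage), with or without a header row.  ``uid`` is assigned as the
    1-based data-row index.  In ``lenient`` mode out-of-range values are
    kept and downgraded to warnings; in ``strict`` mode they raise
    :class:`~heartrisk.exceptions.ValidationError`.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    records: list[PatientRecord] = []
    issues: list[ValidationIssue] = []
    uid = 0
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        tokens = line.split(",")
        if uid == 0 and not records and _looks_like_header(tokens):
            continue
        if len(tokens) not in (len(ATTRIBUTES), len(ATTRIBUTES) + 1):
            raise FormatError(
                f"line {line_no}: expected {len(ATTRIBUTES)} or {len(ATTRIBUTES) + 1} "
                f"fields, found {len(tokens)}"
            )
        uid += 1
        kwargs: dict[str, float | None] = {
            name: _parse_value(tok, line_no, name) for name, tok in zip(ATTRIBUTES, tokens)
        }
        raw_target: int | None = None
        if len(tokens) == len(ATTRIBUTES) + 1:
            parsed = _parse_value(tokens[-1], line_no, TARGET_COLUMN)
            raw_target = None if parsed is None else int(parsed)
        record = PatientRecord(**kwargs, raw_target=raw_target, uid=uid)
        rec_issues = validate_record(record)
        if mode == "strict":
            errors = [i for i in rec_issues if i.severity == "error"]
            if errors:
                first = errors[0]
                raise ValidationError(
                    f"record uid={first.uid}: {first.attribute}={first.observed} {first.constraint}"
                )
        else:
            rec_issues = [replace(i, severity="warning") for i in rec_issues]
        issues.extend(rec_issues)
        records.append(record)
    return records, issues


def write_records(records: Iterable[PatientRecord], path: str | Path, header: bool = True) -> Path:
    """Write records in the UCI dialect; round-trips through :func:`read_records`."""
    path = Path(path)
    lines: list[str] = []
    if header:
        lines.append(",".join(ATTRIBUTES + (TARGET_COLUMN,)))
    for record in records:
        tokens = [_format_value(record.get(a)) for a in ATTRIBUTES]
        tokens.append(_format_value(record.raw_target))
        lines.append(",".join(tokens))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def deduplicate(records: Sequence[PatientRecord]) -> tuple[list[PatientRecord], int]:
    """Drop rows that repeat all 14 data fields, keeping the first occurrence.

    Returns the surviving records (stable order) and the removal count.
    ``uid`` is ignored when comparing rows.
    """
    seen: set[tuple] = set()
    kept: list[PatientRecord] = []
    removed = 0
    for record in records:
        key = record.row_key()
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(record)
    return kept, removed


def binarize_target(raw_target: int) -> int:
    """Collapse the 0–4 disease stage to risk present (1) / absent (0)."""
    if raw_target not in (0, 1, 2, 3, 4):
        raise ValidationError(f"disease stage must be in 0..4, got {raw_target!r}")
    return 0 if raw_target == 0 else 1


def sample_records_path() -> Path:
    """Path to the packaged ten-row sample record file.

    The sample intentionally contains values outside the documented
    ranges (e.g. ``thal`` codes 0/1/2, ``cp`` 0, ``ca`` 4), mirroring
    what published samples of this data look like; reading it in strict
    mode raises.
    """
    return Path(__file__).parent / "data" / "sample_records.csv"
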