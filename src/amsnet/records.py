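"""Questionnaire data model, scoring and I/O.

One *subject-day* pairs a seven-item visual analogue scale (VAS)
questionnaire with a five-item Lake Louise Score (LLS).  Each VAS item is a
mark on a 100 mm line; after orientation 0 mm means minimal and 100 mm
maximal severity for every item.  Two of the seven items ask about fatigue
with different wording and serve as an internal quality-control (QC)
duplicate: a record whose two oriented fatigue responses disagree by more
than the agreement threshold (default 40 mm) is excluded.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per subject-day and the column dialect below; light dataclasses
(:class:`VASRecord`, :class:`LLSRecord`) are provided for record-at-a-time
work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Oriented VAS items, in questionnaire order.
VAS_ITEMS = (
    "headache",
    "nausea_sick",
    "nausea_guts",
    "fatigue_exhausted",
    "fatigue_best",
    "dizziness",
    "sleep",
)
VAS_COLUMNS = tuple(f"vas_{item}" for item in VAS_ITEMS)

#: LLS items (each scored 0-3).
LLS_ITEMS = ("headache", "gi", "fatigue", "dizziness", "sleep")
LLS_COLUMNS = tuple(f"lls_{item}" for item in LLS_ITEMS)

#: Five-symptom composite order used throughout (Table-1 order).
SYMPTOMS = ("sleep", "gi_upset", "dizziness", "headache", "fatigue")

METADATA_COLUMNS = (
    "subject_id",
    "expedition",
    "day",
    "altitude_m",
    "treatment",
    "sex",
    "age_band",
)

#: Full CSV dialect, in column order.
CSV_COLUMNS = METADATA_COLUMNS + VAS_COLUMNS + LLS_COLUMNS

EXPEDITIONS = ("longitudinal", "cross_sectional")
TREATMENTS = ("placebo", "antioxidant", "sildenafil", "unknown")
SEXES = ("male", "female", "missing")
AGE_BANDS = ("<=21", "22-25", ">=26", "missing")

#: Printed direction of each question on the instrument.  ``reversed`` means
#: the high-severity anchor sits at the 0 mm end, so the raw measurement
#: (always taken from the left end of the line) must be mapped v -> 100 - v.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "headache": "normal",            # "no headache at all" -> "worst headache ever"
    "nausea_sick": "reversed",       # "I really want to be sick" -> "don't feel sick at all"
    "nausea_guts": "reversed",       # "my guts are really bad" -> "my guts are fine"
    "fatigue_exhausted": "reversed", # "I'm totally exhausted" -> "I'm full of energy"
    "fatigue_best": "normal",        # "I'm at my best" -> "I'm at my worst"
    "dizziness": "normal",           # "no dizziness at all" -> "more dizzy than ever"
    "sleep": "reversed",             # "worst night's sleep ever" -> "best night's sleep ever"
}

QC_THRESHOLD_MM = 40.0


class ValidationError(ValueError):
    """A record (or file row) violated the data-model invariants."""


@dataclass(frozen=True)
class VASRecord:
    """One subject-day's oriented VAS measurements plus metadata."""

    subject_id: str
    expedition: str
    day: int | None
    altitude_m: float
    treatment: str
    sex: str
    age_band: str
    items: tuple[float, ...]  # seven oriented mm values, VAS_ITEMS order

    def __post_init__(self) -> None:
        if self.expedition not in EXPEDITIONS:
            raise ValidationError(f"unknown expedition {self.expedition!r}")
        if len(self.items) != len(VAS_ITEMS):
            raise ValidationError("VASRecord needs exactly seven items")
        for name, v in zip(VAS_ITEMS, self.items):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"subject {self.subject_id}: VAS item {name}={v} outside [0, 100]"
                )

    def item(self, name: str) -> float:
        return self.items[VAS_ITEMS.index(name)]


@dataclass(frozen=True)
class LLSRecord:
    """One subject-day's five Lake Louise item scores (each 0-3)."""

    subject_id: str
    day: int | None
    items: tuple[int, ...]  # LLS_ITEMS order

    def __post_init__(self) -> None:
        if len(self.items) != len(LLS_ITEMS):
            raise ValidationError("LLSRecord needs exactly five items")
        for name, v in zip(LLS_ITEMS, self.items):
            if v not in (0, 1, 2, 3):
                raise ValidationError(
                    f"subject {self.subject_id}: LLS item {name}={v} not in 0..3"
                )

    def item(self, name: str) -> int:
        return self.items[LLS_ITEMS.index(name)]


@dataclass(frozen=True)
class SymptomProfile:
    """Five oriented severities in mm; duplicate items averaged."""

    sleep: float
    gi_upset: float
    dizziness: float
    headache: float
    fatigue: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, s) for s in SYMPTOMS)


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------

def orient_items(
    raw_items: Mapping[str, float] | Sequence[float],
    direction_map: Mapping[str, str] = DEFAULT_DIRECTIONS,
) -> dict[str, float]:
    """Map raw line positions to oriented severities (0 = no symptom).

    Items whose printed scale runs from severe to mild (``reversed``) are
    mapped ``v -> 100 - v``; ``normal`` items pass through.  Orientation is
    an involution on the reversed items.
    """
    if not isinstance(raw_items, Mapping):
        raw_items = dict(zip(VAS_ITEMS, raw_items))
    out: dict[str, float] = {}
    for name, v in raw_items.items():
        direction = direction_map.get(name, "normal")
        if direction not in ("normal", "reversed"):
            raise ValidationError(f"bad direction {direction!r} for item {name}")
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"VAS item {name}={v} outside [0, 100]")
        out[name] = 100.0 - v if direction == "reversed" else v
    return out


def orient_frame(
    df: pd.DataFrame, direction_map: Mapping[str, str] = DEFAULT_DIRECTIONS
) -> pd.DataFrame:
    """Vectorised :func:`orient_items` over the ``vas_*`` columns."""
    out = df.copy()
    for item in VAS_ITEMS:
        col = f"vas_{item}"
        vals = out[col].to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 100)
        if bad.any():
            raise ValidationError(
                f"row {out.index[bad][0]}: VAS item {item} outside [0, 100]"
            )
        if direction_map.get(item, "normal") == "reversed":
            out[col] = 100.0 - vals
    return out


def qc_difference(record: VASRecord | pd.DataFrame) -> float | pd.Series:
    """Absolute disagreement (mm) between the two oriented fatigue items."""
    if isinstance(record, VASRecord):
        return abs(record.item("fatigue_exhausted") - record.item("fatigue_best"))
    return (record["vas_fatigue_exhausted"] - record["vas_fatigue_best"]).abs()


def qc_filter(
    record: VASRecord | pd.DataFrame, threshold_mm: float = QC_THRESHOLD_MM
) -> bool | pd.Series:
    """QC concordance filter: ``True`` = pass.

    A record passes iff the two oriented duplicate-fatigue responses agree to
    within ``threshold_mm`` (inclusive: a difference of exactly the threshold
    passes, reading "minimum agreement required" as an inclusive bound).
    """
    return qc_difference(record) <= threshold_mm


def total_vas(
    record: VASRecord | pd.DataFrame,
    weights: Sequence[float] | Mapping[str, float] | None = None,
) -> float | pd.Series:
    """Weighted total VAS score in mm (unit weights: range 0-700).

    ``weights`` follows :data:`VAS_ITEMS` order (or maps item names); it is
    the hook for exploring alternative symptom weightings.
    """
    w = _resolve_weights(weights)
    if isinstance(record, VASRecord):
        return float(np.dot(w, record.items))
    mat = record[list(VAS_COLUMNS)].to_numpy(dtype=float)
    return pd.Series(mat @ w, index=record.index, name="total_vas")


def _resolve_weights(weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(VAS_ITEMS))
    if isinstance(weights, Mapping):
        weights = [weights.get(item, 1.0) for item in VAS_ITEMS]
    w = np.asarray(list(weights), dtype=float)
    if w.shape != (len(VAS_ITEMS),):
        raise ValidationError("need one weight per VAS item")
    if (w < 0).any():
        raise ValidationError("negative symptom weights are not allowed")
    return w


def to_symptom_profile(record: VASRecord) -> SymptomProfile:
    """Collapse the seven items to the five symptoms (duplicates averaged)."""
    return SymptomProfile(
        sleep=record.item("sleep"),
        gi_upset=(record.item("nausea_sick") + record.item("nausea_guts")) / 2.0,
        dizziness=record.item("dizziness"),
        headache=record.item("headache"),
        fatigue=(record.item("fatigue_exhausted") + record.item("fatigue_best")) / 2.0,
    )


def symptom_profile_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Five-symptom profile table (columns in :data:`SYMPTOMS` order)."""
    return pd.DataFrame(
        {
            "sleep": df["vas_sleep"].astype(float),
            "gi_upset": (df["vas_nausea_sick"] + df["vas_nausea_guts"]) / 2.0,
            "dizziness": df["vas_dizziness"].astype(float),
            "headache": df["vas_headache"].astype(float),
            "fatigue": (df["vas_fatigue_exhausted"] + df["vas_fatigue_best"]) / 2.0,
        },
        index=df.index,
    )


def lls_total(record: LLSRecord | pd.DataFrame) -> int | pd.Series:
    """Total Lake Louise Score (0-15)."""
    if isinstance(record, LLSRecord):
        return int(sum(record.items))
    return record[list(LLS_COLUMNS)].sum(axis=1)


def ams_case(record: LLSRecord | pd.DataFrame) -> bool | pd.Series:
    """AMS case definition: LLS total > 2 with headache present (> 0)."""
    if isinstance(record, LLSRecord):
        return sum(record.items) > 2 and record.item("headache") > 0
    total = record[list(LLS_COLUMNS)].sum(axis=1)
    return (total > 2) & (record["lls_headache"] > 0)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

@dataclass
class RowError:
    line: int  # 1-based physical line in the CSV (header = line 1)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


class FileValidationError(ValidationError):
    """Raised when a CSV contains malformed rows (report attached)."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        preview = "; ".join(str(e) for e in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} malformed row(s): {preview}{more}")


def _validate_row(row: pd.Series) -> list[str]:
    problems: list[str] = []
    if not str(row["subject_id"]).strip():
        problems.append("empty subject_id")
    if row["expedition"] not in EXPEDITIONS:
        problems.append(f"bad expedition {row['expedition']!r}")
    if row["expedition"] == "longitudinal" and pd.isna(row["day"]):
        problems.append("longitudinal record without a day index")
    if row["treatment"] not in TREATMENTS:
        problems.append(f"bad treatment {row['treatment']!r}")
    if row["sex"] not in SEXES:
        problems.append(f"bad sex {row['sex']!r}")
    if row["age_band"] not in AGE_BANDS:
        problems.append(f"bad age_band {row['age_band']!r}")
    for col in VAS_COLUMNS:
        v = row[col]
        if pd.isna(v) or not 0.0 <= float(v) <= 100.0:
            problems.append(f"{col}={v} outside [0, 100]")
    for col in LLS_COLUMNS:
        v = row[col]
        if pd.isna(v) or float(v) not in (0.0, 1.0, 2.0, 3.0):
            problems.append(f"{col}={v} not an integer in 0..3")
    return problems


def read_records(path, skip_bad_rows: bool = False) -> pd.DataFrame:
    """Read a questionnaire CSV (items stored oriented, 0 = no symptom).

    Rows failing validation are collected with their physical line numbers;
    by default any failure aborts the read with a
    :class:`FileValidationError`, with ``skip_bad_rows`` the offending rows
    are dropped and reported at warning level.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "expedition": str, "treatment": str,
               "sex": str, "age_band": str},
        keep_default_na=True,
    )
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    if df.empty:
        logger.warning("%s: header-only file, no records", path)
        return _finalise_frame(df)
    for col in ("sex", "age_band"):
        df[col] = df[col].fillna("missing")
    df["treatment"] = df["treatment"].fillna("unknown")
    errors: list[RowError] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        for msg in _validate_row(row):
            errors.append(RowError(line=pos + 2, message=msg))
    if errors:
        if not skip_bad_rows:
            raise FileValidationError(errors)
        bad_lines = {e.line for e in errors}
        logger.warning("%s: dropping %d malformed row(s)", path, len(bad_lines))
        keep = [i for i in range(len(df)) if i + 2 not in bad_lines]
        df = df.iloc[keep]
    return _finalise_frame(df)


def _finalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["day"] = df.get("day", pd.Series(dtype=float))
    df["day"] = pd.array(
        [int(v) if pd.notna(v) else None for v in df["day"]], dtype="Int64"
    )
    for col in VAS_COLUMNS:
        df[col] = df[col].astype(float) if col in df else np.nan
    for col in LLS_COLUMNS:
        df[col] = df[col].astype(int) if len(df) else df.get(col, pd.Series(dtype=int))
    return df.reset_index(drop=True)


def write_records(df: pd.DataFrame, path) -> None:
    """Write records in the canonical CSV dialect (lossless round-trip)."""
    if df.empty and not set(CSV_COLUMNS) <= set(df.columns):
        raise ValidationError("refusing to write an empty, column-less table")
    out = df[list(CSV_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format="%.1f")


def records_from_frame(df: pd.DataFrame) -> list[tuple[VASRecord, LLSRecord]]:
    """Materialise typed (VASRecord, LLSRecord) pairs from a records table."""
    pairs = []
    for _, row in df.iterrows():
        day = None if pd.isna(row["day"]) else int(row["day"])
        vas = VASRecord(
            subject_id=row["subject_id"],
            expedition=row["expedition"],
            day=day,
            altitude_m=float(row["altitude_m"]),
            treatment=row["treatment"],
            sex=row["sex"],
            age_band=row["age_band"],
            items=tuple(float(row[c]) for c in VAS_COLUMNS),
        )
        lls = LLSRecord(
            subject_id=row["subject_id"],
            day=day,
            items=tuple(int(row[c]) for c in LLS_COLUMNS),
        )
        pairs.append((vas, lls))
    return pairs
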