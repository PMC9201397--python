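"""Subject-level cohort tables: canonical schema, validation, CSV round-trip.

The canonical flat table has one row per subject with the columns

``subject_id, sex, age, height_m, weight_kg, alm_dxa_kg, alm_bia_kg,
ffm_dxa_kg, ffm_bia_kg, bmi, fat_pct``

where ``weight_kg``, ``bmi`` and ``fat_pct`` are optional.  All other modules
consume :class:`Cohort` objects produced here (or by the synthetic generator).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import (
    CohortError,
    EmptyCohortError,
    RowValidationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "SubjectRecord",
    "ExcludedRow",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]


class Sex(str, Enum):
    """Biological sex stratum; the analysis recognises exactly two."""

    MALE = "male"
    FEMALE = "female"


#: Aliases accepted (case-insensitively) when parsing the ``sex`` column.
_SEX_ALIASES = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
}

REQUIRED_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "height_m",
    "alm_dxa_kg",
    "alm_bia_kg",
    "ffm_dxa_kg",
    "ffm_bia_kg",
)
OPTIONAL_COLUMNS = ("weight_kg", "bmi", "fat_pct")
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS


def parse_sex(value: str) -> Sex:
    """Parse a sex label case-insensitively from {m, male, f, female}."""
    try:
        return _SEX_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognised sex label {value!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's paired device measurements and covariates.

    Invariants (checked at construction):

    * ``height_m`` and every mass value are strictly positive;
    * appendicular lean mass is strictly below fat-free mass on both
      devices (appendicular lean is a strict subset of fat-free mass);
    * optional covariates, when present, are strictly positive.
    """

    subject_id: str
    sex: Sex
    age: float
    height_m: float
    alm_dxa_kg: float
    alm_bia_kg: float
    ffm_dxa_kg: float
    ffm_bia_kg: float
    weight_kg: Optional[float] = None
    bmi: Optional[float] = None
    fat_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", parse_sex(self.sex))
        if not (self.height_m > 0):
            raise CohortError(f"{self.subject_id}: height must be > 0")
        for name in ("alm_dxa_kg", "alm_bia_kg", "ffm_dxa_kg", "ffm_bia_kg"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise CohortError(f"{self.subject_id}: {name} must be finite and > 0")
        if not self.alm_dxa_kg < self.ffm_dxa_kg:
            raise CohortError(f"{self.subject_id}: alm_dxa_kg must be < ffm_dxa_kg")
        if not self.alm_bia_kg < self.ffm_bia_kg:
            raise CohortError(f"{self.subject_id}: alm_bia_kg must be < ffm_bia_kg")
        for name in ("weight_kg", "bmi", "fat_pct"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise CohortError(f"{self.subject_id}: {name} must be > 0 when present")


@dataclass(frozen=True)
class ExcludedRow:
    """Provenance of one dropped input row (0-based data-row index)."""

    row_index: int
    subject_id: Optional[str]
    reason: str


@dataclass(frozen=True)
class Cohort:
    """An ordered, validated collection of :class:`SubjectRecord`.

    ``excluded`` records rows dropped during reading so that
    ``len(records) + len(excluded)`` equals the input row count.
    """

    records: tuple
    provenance: str = ""
    excluded: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "excluded", tuple(self.excluded))
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate subject_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def sex_records(self, sex: Sex) -> tuple:
        return tuple(r for r in self.records if r.sex is sex)

    @property
    def n_male(self) -> int:
        return len(self.sex_records(Sex.MALE))

    @property
    def n_female(self) -> int:
        return len(self.sex_records(Sex.FEMALE))

    def to_frame(self) -> pd.DataFrame:
        """Flat table in canonical column order; sex as 'male'/'female'."""
        rows = []
        for r in self.records:
            row = {f.name: getattr(r, f.name) for f in fields(SubjectRecord)}
            row["sex"] = r.sex.value
            rows.append(row)
        return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def _parse_float(raw, row_index: int, column: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        raise RowValidationError(row_index, f"missing required value in column '{column}'")
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise RowValidationError(
            row_index, f"non-numeric value {raw!r} in column '{column}'"
        )
    if not math.isfinite(value):
        raise RowValidationError(row_index, f"non-finite value in column '{column}'")
    return value


def _parse_optional_float(raw) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return None
    return float(raw)


def read_cohort(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    height_unit: str = "m",
    exclusion_path=None,
) -> Cohort:
    """Read a delimiter-separated cohort table, excluding unusable rows.

    Parameters
    ----------
    path:
        CSV file with a header row (RFC-4180 style, UTF-8, '.' decimals).
    column_map:
        Optional mapping ``{column name in file: canonical column name}``
        applied before schema validation.
    height_unit:
        ``"m"`` (default) or ``"cm"``; centimetre heights are converted.
    exclusion_path:
        When given, dropped rows are also written there as a sidecar CSV.

    Rows with missing or non-numeric required fields, unknown sex labels,
    or physically impossible values are excluded (not fatal) and reported
    in ``Cohort.excluded`` with their 0-based data-row index.

    Raises
    ------
    SchemaError
        If a required column is absent after renaming.
    EmptyCohortError
        If no usable rows remain.
    """
    path = Path(path)
    if height_unit not in ("m", "cm"):
        raise SchemaError(f"height_unit must be 'm' or 'cm', got {height_unit!r}")
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' not found in {path}")

    records: list[SubjectRecord] = []
    excluded: list[ExcludedRow] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        sid = raw.get("subject_id")
        sid = None if sid is None or str(sid).strip() == "" else str(sid).strip()
        try:
            if sid is None:
                raise RowValidationError(idx, "missing subject_id")
            try:
                sex = parse_sex(raw["sex"])
            except (ValueError, TypeError):
                raise RowValidationError(idx, f"unrecognised sex label {raw.get('sex')!r}")
            values = {
                col: _parse_float(raw.get(col), idx, col)
                for col in REQUIRED_COLUMNS
                if col not in ("subject_id", "sex")
            }
            if height_unit == "cm":
                values["height_m"] = values["height_m"] / 100.0
            optional = {}
            for col in OPTIONAL_COLUMNS:
                try:
                    optional[col] = _parse_optional_float(raw.get(col))
                except (TypeError, ValueError):
                    raise RowValidationError(
                        idx, f"non-numeric value {raw.get(col)!r} in column '{col}'"
                    )
            record = SubjectRecord(subject_id=sid, sex=sex, **values, **optional)
        except RowValidationError as err:
            excluded.append(ExcludedRow(idx, sid, str(err)))
            continue
        except CohortError as err:
            excluded.append(ExcludedRow(idx, sid, str(err)))
            continue
        records.append(record)

    if not records:
        raise EmptyCohortError(f"no usable rows in {path} ({len(excluded)} excluded)")
    logger.info(
        "read %d records from %s (%d rows excluded)", len(records), path, len(excluded)
    )
    for ex in excluded:
        logger.warning("excluded %s", ex)
    if exclusion_path is not None:
        pd.DataFrame([ex.__dict__ for ex in excluded]).to_csv(
            exclusion_path, index=False
        )
    return Cohort(records=tuple(records), provenance=str(path), excluded=tuple(excluded))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as canonical CSV; round-trips bit-for-bit via read_cohort."""
    if cohort.n == 0:
        raise EmptyCohortError("refusing to write an empty cohort")
    cohort.to_frame().to_csv(path, index=False)


def with_provenance(cohort: Cohort, provenance: str) -> Cohort:
    return replace(cohort, provenance=provenance)
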