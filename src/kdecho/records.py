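"""Tidy per-measurement echo records and their CSV round trip.

One row per animal x study day: identifier, dose group, body weight and the
raw echo measurements (mm, or percent for ejection fraction).  Missing
measurements are empty CSV cells.  The canonical in-memory container is a
pandas DataFrame with the exact column set below; :class:`EchoRecord` gives
a typed single-row view for callers that prefer objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import math

import numpy as np
import pandas as pd

from .config import MEASUREMENTS, LENGTH_MEASUREMENTS, VESSEL_PAIRS

#: Exact CSV header, in order.
COHORT_COLUMNS: tuple[str, ...] = (
    "animal_id",
    "group",
    "day",
    "body_weight_g",
    *MEASUREMENTS,
)

_TOL = 1e-9


class CohortValidationError(ValueError):
    """A cohort table row violates a structural invariant."""


@dataclass
class EchoRecord:
    """One animal x day row of raw echo measurements."""

    animal_id: str
    group: str
    day: int
    body_weight_g: float
    coronary_inner_d_mm: Optional[float] = None
    coronary_outer_d_mm: Optional[float] = None
    carotid_inner_d_mm: Optional[float] = None
    carotid_outer_d_mm: Optional[float] = None
    carotid_upper_wall_mm: Optional[float] = None
    carotid_lower_wall_mm: Optional[float] = None
    aorta_inner_d_mm: Optional[float] = None
    aorta_outer_d_mm: Optional[float] = None
    aorta_upper_wall_mm: Optional[float] = None
    aorta_lower_wall_mm: Optional[float] = None
    ejection_fraction_pct: Optional[float] = None


def records_to_frame(records: Iterable[EchoRecord]) -> pd.DataFrame:
    """Build the canonical cohort DataFrame from :class:`EchoRecord` rows."""
    rows = [
        {col: getattr(r, col) for col in COHORT_COLUMNS} for r in records
    ]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return _normalize(df)


def frame_to_records(df: pd.DataFrame) -> list[EchoRecord]:
    """Typed row objects from a cohort DataFrame (NaN becomes None)."""
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in COHORT_COLUMNS:
            val = row[col]
            if isinstance(val, float) and math.isnan(val):
                val = None
            kwargs[col] = val
        kwargs["day"] = int(kwargs["day"])
        out.append(EchoRecord(**kwargs))
    return out


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["animal_id"] = df["animal_id"].astype(str)
    df["group"] = df["group"].astype(str)
    df["day"] = df["day"].astype(np.int64)
    for col in ("body_weight_g", *MEASUREMENTS):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(np.float64)
    return df.reset_index(drop=True)


def validate_cohort(df: pd.DataFrame) -> None:
    """Check structural invariants, naming the first offending data row.

    Row numbers are 1-based over data rows (header excluded).
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")

    def _fail(mask: pd.Series, rule: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise CohortValidationError(f"row {row}: {rule}")

    _fail(df["body_weight_g"].isna() | (df["body_weight_g"] <= 0),
          "body_weight_g must be present and > 0")
    _fail(df["day"] < 0, "day must be >= 0")
    for m in LENGTH_MEASUREMENTS:
        _fail(df[m].notna() & (df[m] <= 0), f"{m} must be > 0 when present")
    ef = df["ejection_fraction_pct"]
    _fail(ef.notna() & ((ef <= 0) | (ef > 100)),
          "ejection_fraction_pct must be in (0, 100]")
    for vessel, (inner, outer) in VESSEL_PAIRS.items():
        both = df[inner].notna() & df[outer].notna()
        _fail(both & (df[outer] < df[inner] - _TOL),
              f"{outer} must be >= {inner}")


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a validated cohort table as UTF-8 CSV (missing = empty cell)."""
    df = _normalize(df[list(COHORT_COLUMNS)])
    validate_cohort(df)
    df.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str})
    got = list(df.columns)
    if got != list(COHORT_COLUMNS):
        raise CohortValidationError(
            f"unexpected header: {got!r} (expected {list(COHORT_COLUMNS)!r})"
        )
    if df.empty:
        return _normalize(pd.DataFrame(columns=list(COHORT_COLUMNS)))
    df = _normalize(df)
    validate_cohort(df)
    return df
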