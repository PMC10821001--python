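"""CSV input/output for dose records and conversion results.

The on-disk format is a plain comma-separated file with a header row.
Required columns are ``exam_id``, ``dlp_mgycm`` and an age given either
as decimal years (``age_years``) or as a pair of ISO-8601 dates
(``birth_date``, ``scan_date``) from which the age is computed as
elapsed days / 365.2425.  Optional columns: ``ed_device_msv``, ``sex``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import ConversionResult, DoseRecord
from .exceptions import ValidationError

__all__ = ["RowError", "read_records", "records_frame", "write_records", "results_frame"]

DAYS_PER_YEAR = 365.2425

REQUIRED_COLUMNS = ("exam_id", "dlp_mgycm")


@dataclass(frozen=True)
class RowError:
    """A skipped input row: zero-based data row index plus the reason."""

    row: int
    message: str


def _row_age(row, has_age: bool) -> float:
    if has_age and not pd.isna(row.get("age_years")):
        return float(row["age_years"])
    birth = pd.to_datetime(row["birth_date"])
    scan = pd.to_datetime(row["scan_date"])
    if pd.isna(birth) or pd.isna(scan):
        raise ValueError("unparseable birth_date/scan_date")
    return (scan - birth).days / DAYS_PER_YEAR


def read_records(path: str | Path) -> tuple[list[DoseRecord], list[RowError]]:
    """Read dose records from CSV.

    Returns the parsed records plus a list of :class:`RowError` for
    rows that could not be parsed (those rows are skipped, not fatal).
    A missing required *column* raises :class:`ValidationError` naming
    the column.
    """
    frame = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")
    has_age = "age_years" in frame.columns
    has_dates = "birth_date" in frame.columns and "scan_date" in frame.columns
    if not has_age and not has_dates:
        raise ValidationError(
            f"{path}: missing required column 'age_years' "
            "(or 'birth_date' + 'scan_date')"
        )

    records: list[DoseRecord] = []
    errors: list[RowError] = []
    for i, row in frame.iterrows():
        try:
            age = _row_age(row, has_age)
            dlp = float(row["dlp_mgycm"])
            device = row.get("ed_device_msv")
            device = None if device is None or pd.isna(device) else float(device)
            sex = row.get("sex")
            sex = None if sex is None or pd.isna(sex) else str(sex)
            records.append(
                DoseRecord(
                    exam_id=str(row["exam_id"]),
                    age_years=age,
                    dlp=dlp,
                    device_ed=device,
                    sex=sex,
                )
            )
        except (ValueError, TypeError, ValidationError) as exc:
            errors.append(RowError(row=int(i), message=str(exc)))
    return records, errors


def records_frame(records) -> pd.DataFrame:
    """Dose records as a DataFrame in the standard column layout."""
    return pd.DataFrame(
        {
            "exam_id": [r.exam_id for r in records],
            "age_years": [r.age_years for r in records],
            "dlp_mgycm": [r.dlp for r in records],
            "ed_device_msv": [
                np.nan if r.device_ed is None else r.device_ed for r in records
            ],
            "sex": [r.sex for r in records],
        }
    )


def write_records(records, path: str | Path) -> None:
    """Write dose records to CSV in the standard column layout."""
    records_frame(records).to_csv(path, index=False)


def results_frame(records, results: list[ConversionResult]) -> pd.DataFrame:
    """Input columns plus per-method ``factor_*`` and ``ed_*_msv`` columns."""
    frame = records_frame(records)
    frame["integer_age"] = [res.integer_age for res in results]
    methods: list[str] = []
    for res in results:
        for m in res.factors:
            if m not in methods:
                methods.append(m)
        for m in res.ed:
            if m not in methods:
                methods.append(m)
    for m in methods:
        frame[f"factor_{m}"] = [res.factors.get(m, np.nan) for res in results]
        frame[f"ed_{m}_msv"] = [res.ed.get(m, np.nan) for res in results]
    return frame
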