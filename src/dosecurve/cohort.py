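"""Age binning and per-bin cohort statistics.

Dose surveys report medians per integer year of age and per diagnostic
reference level (DRL) age group (0, 1-4, 5-9, 10-14 years); device-style
ED/DLP ratios are summarized per phantom age bin.  Integer ages are the
floor of the decimal age: a child aged 2 years 6 months counts as 2.

Summary conventions: median of an even-sized group is the mean of the
two central order statistics; SD uses the n-1 divisor; the coefficient
of variation is 100*SD/mean (%).  Empty bins are reported with n=0 so
per-age profiles over 0..14 are always complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anchors import PhantomBinTable, RADIMETRICS_BRAIN_BINS
from .estimation import ed_dlp_ratio
from .exceptions import ValidationError

__all__ = [
    "integer_age",
    "AgeBinScheme",
    "assign_bin",
    "summarize",
    "ratio_profile",
]

MAX_AGE = 15.0


def integer_age(age_years: float) -> int:
    """Age in completed integer years (floor of the decimal age)."""
    if not age_years >= 0:
        raise ValidationError(f"age must be >= 0, got {age_years}")
    return int(math.floor(age_years))


@dataclass(frozen=True)
class AgeBinScheme:
    """Contiguous half-open age bins covering 0 to 15 years.

    ``kind`` selects the assignment convention: ``integer_year`` and
    ``drl_group`` assign on the floored integer age; ``phantom_bin``
    and ``custom`` assign on the decimal age directly.
    """

    kind: str
    bins: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        if not self.bins:
            raise ValidationError("bin scheme must not be empty")
        for label, lo, hi in self.bins:
            if not lo < hi:
                raise ValidationError(f"bin '{label}': lower {lo} must be < upper {hi}")
        for (l1, _, hi), (l2, lo2, _) in zip(self.bins, self.bins[1:]):
            if hi != lo2:
                raise ValidationError(
                    f"bins must be contiguous: '{l1}' ends at {hi}, '{l2}' starts at {lo2}"
                )
        if self.bins[0][1] != 0 or self.bins[-1][2] != MAX_AGE:
            raise ValidationError(f"bin scheme must cover [0, {MAX_AGE}) exactly")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bins)

    @classmethod
    def integer_year(cls) -> "AgeBinScheme":
        """One bin per integer year, 0 through 14."""
        return cls(
            kind="integer_year",
            bins=tuple((str(k), float(k), float(k + 1)) for k in range(15)),
        )

    @classmethod
    def drl_group(cls) -> "AgeBinScheme":
        """DRL age groups 0, 1-4, 5-9, 10-14 years."""
        return cls(
            kind="drl_group",
            bins=(("0", 0.0, 1.0), ("1-4", 1.0, 5.0), ("5-9", 5.0, 10.0), ("10-14", 10.0, 15.0)),
        )

    @classmethod
    def phantom_bin(cls, table: PhantomBinTable = RADIMETRICS_BRAIN_BINS) -> "AgeBinScheme":
        """Bins of a device phantom table (sub-year edges, decimal-age assignment)."""
        return cls(
            kind="phantom_bin",
            bins=tuple(
                (f"{lo:g}-{hi:g}", lo, hi) for lo, hi, _ in table.bins
            ),
        )

    @classmethod
    def custom(cls, bins) -> "AgeBinScheme":
        return cls(kind="custom", bins=tuple(bins))


def assign_bin(age_years: float, scheme: AgeBinScheme) -> str:
    """Label of the unique bin containing ``age_years``."""
    key = float(integer_age(age_years)) if scheme.kind in ("integer_year", "drl_group") else float(age_years)
    if not 0 <= key < MAX_AGE:
        raise ValidationError(
            f"age {age_years} outside scheme coverage [0, {MAX_AGE})"
        )
    for label, lo, hi in scheme.bins:
        if lo <= key < hi:
            return label
    raise ValidationError(f"age {age_years} not covered by scheme")  # pragma: no cover


def _bin_stats(values: np.ndarray) -> dict:
    n = len(values)
    if n == 0:
        return {"n": 0, "median": np.nan, "mean": np.nan, "sd": np.nan, "cv_percent": np.nan}
    median = float(np.median(values))
    mean = float(np.mean(values))
    sd = 0.0 if n == 1 else float(np.std(values, ddof=1))
    cv = 0.0 if mean == 0 else 100.0 * sd / abs(mean)
    return {"n": n, "median": median, "mean": mean, "sd": sd, "cv_percent": cv}


def summarize(ages, values, scheme: AgeBinScheme) -> pd.DataFrame:
    """Per-bin n/median/mean/SD/CV of ``values`` grouped by age bin.

    ``ages`` and ``values`` are parallel sequences; NaN values are
    dropped (their records do not contribute to any bin's statistics).
    Returns one row per scheme bin, in scheme order, empty bins with
    ``n=0`` and NaN statistics.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape:
        raise ValidationError("ages and values must have equal length")
    keep = ~np.isnan(values)
    ages, values = ages[keep], values[keep]
    labels = [assign_bin(a, scheme) for a in ages]
    rows = []
    for label in scheme.labels:
        in_bin = values[[lab == label for lab in labels]]
        rows.append({"bin": label, **_bin_stats(in_bin)})
    return pd.DataFrame(rows)


def ratio_profile(records, scheme: AgeBinScheme) -> pd.DataFrame:
    """Per-bin summary of device ED/DLP ratios.

    Uses records with a device ED and a positive DLP; returns the same
    layout as :func:`summarize`.  With no eligible records, every bin
    has ``n=0``.
    """
    eligible = [r for r in records if r.device_ed is not None and r.dlp > 0]
    ages = [r.age_years for r in eligible]
    ratios = [ed_dlp_ratio(r.device_ed, r.dlp) for r in eligible]
    if not eligible:
        return summarize([], [], scheme)
    return summarize(ages, ratios, scheme)
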