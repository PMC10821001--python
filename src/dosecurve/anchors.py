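"""Anchor tables of DLP-to-ED conversion factors and device phantom bins.

The ICRP publishes dose-length-product (DLP) to effective-dose (ED)
conversion factors ("k-factors", mSv/mGy/cm) for children at 0, 1, 5 and
10 years of age.  :class:`AnchorTable` holds such a set of (age, factor)
anchors for one body region; the brain-CT defaults are bundled as
:data:`BRAIN_ANCHORS`.

Radiation dose management systems that estimate the ED by Monte Carlo
simulation select a computational phantom by age, which makes their
ED/DLP ratio piecewise constant in age.  :class:`PhantomBinTable`
represents that behaviour as contiguous age bins with one ratio each;
the brain-CT defaults observed for such a system are bundled as
:data:`RADIMETRICS_BRAIN_BINS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "AnchorTable",
    "PhantomBinTable",
    "BRAIN_ANCHORS",
    "RADIMETRICS_BRAIN_BINS",
    "load_anchor_table",
    "load_phantom_bins",
]


@dataclass(frozen=True)
class AnchorTable:
    """Ordered (age, conversion factor) anchors for one body region.

    Parameters
    ----------
    entries
        Sequence of ``(age_years, factor)`` pairs, ages strictly
        increasing and non-negative, factors positive (mSv/mGy/cm).
    region_label
        Free-text label for the body region, e.g. ``"brain"``.
    """

    entries: tuple[tuple[float, float], ...]
    region_label: str = ""

    def __post_init__(self):
        entries = tuple((float(a), float(f)) for a, f in self.entries)
        object.__setattr__(self, "entries", entries)
        if len(entries) < 2:
            raise ValidationError(
                f"anchor table needs at least 2 entries, got {len(entries)}"
            )
        for i, (age, factor) in enumerate(entries):
            if age < 0:
                raise ValidationError(f"anchor row {i}: negative age {age}")
            if not factor > 0:
                raise ValidationError(
                    f"anchor row {i}: conversion factor must be > 0, got {factor}"
                )
        ages = [a for a, _ in entries]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise ValidationError("anchor ages must be strictly increasing")

    @property
    def ages(self) -> np.ndarray:
        return np.array([a for a, _ in self.entries], dtype=float)

    @property
    def factors(self) -> np.ndarray:
        return np.array([f for _, f in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PhantomBinTable:
    """Contiguous age bins with one ED/DLP ratio per bin.

    Bins are half-open ``[lower, upper)`` except the last, which is
    closed at its upper edge.
    """

    bins: tuple[tuple[float, float, float], ...]
    label: str = field(default="", compare=False)

    def __post_init__(self):
        bins = tuple((float(lo), float(hi), float(r)) for lo, hi, r in self.bins)
        object.__setattr__(self, "bins", bins)
        if not bins:
            raise ValidationError("phantom bin table must not be empty")
        for i, (lo, hi, ratio) in enumerate(bins):
            if not lo < hi:
                raise ValidationError(f"bin row {i}: lower {lo} must be < upper {hi}")
            if not ratio > 0:
                raise ValidationError(f"bin row {i}: ratio must be > 0, got {ratio}")
        for i, ((_, hi, _), (lo2, _, _)) in enumerate(zip(bins, bins[1:])):
            if hi != lo2:
                raise ValidationError(
                    f"bins must be contiguous: row {i} ends at {hi}, "
                    f"row {i + 1} starts at {lo2}"
                )

    @property
    def lower(self) -> float:
        return self.bins[0][0]

    @property
    def upper(self) -> float:
        return self.bins[-1][1]

    def factor_at(self, age: float) -> float:
        """Ratio of the bin containing ``age`` (last bin top-closed)."""
        age = float(age)
        if not self.lower <= age <= self.upper:
            raise ValidationError(
                f"age {age} outside phantom-bin range [{self.lower}, {self.upper}]"
            )
        for lo, hi, ratio in self.bins[:-1]:
            if lo <= age < hi:
                return ratio
        return self.bins[-1][2]


#: ICRP brain-CT conversion-factor anchors (mSv/mGy/cm at 0, 1, 5, 10 years).
BRAIN_ANCHORS = AnchorTable(
    entries=((0.0, 0.011), (1.0, 0.0067), (5.0, 0.0040), (10.0, 0.0032)),
    region_label="brain",
)

#: Observed per-phantom ED/DLP ratios of a Monte-Carlo dose management
#: system for pediatric brain CT (mean ratio per phantom age bin).
RADIMETRICS_BRAIN_BINS = PhantomBinTable(
    bins=(
        (0.0, 0.5, 0.0115),
        (0.5, 2.5, 0.0076),
        (2.5, 7.5, 0.0047),
        (7.5, 12.5, 0.0036),
        (12.5, 15.0, 0.0028),
    ),
    label="brain",
)


def load_anchor_table(path: str | Path) -> AnchorTable:
    """Load an :class:`AnchorTable` from a JSON file.

    Expected layout::

        {"region": "brain", "anchors": [[0, 0.011], [1, 0.0067], ...]}
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    if "anchors" not in payload:
        raise ValidationError(f"{path}: missing 'anchors' key")
    rows = payload["anchors"]
    entries = []
    for i, row in enumerate(rows):
        try:
            age, factor = float(row[0]), float(row[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise ValidationError(f"{path}: anchor row {i}: malformed entry {row!r}") from exc
        entries.append((age, factor))
    return AnchorTable(tuple(entries), region_label=str(payload.get("region", "")))


def load_phantom_bins(path: str | Path) -> PhantomBinTable:
    """Load a :class:`PhantomBinTable` from a JSON file.

    Expected layout::

        {"label": "brain", "bins": [[0, 0.5, 0.0115], ...]}
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    if "bins" not in payload:
        raise ValidationError(f"{path}: missing 'bins' key")
    rows = payload["bins"]
    bins = []
    for i, row in enumerate(rows):
        try:
            lo, hi, ratio = float(row[0]), float(row[1]), float(row[2])
        except (TypeError, ValueError, IndexError) as exc:
            raise ValidationError(f"{path}: bin row {i}: malformed entry {row!r}") from exc
        bins.append((lo, hi, ratio))
    return PhantomBinTable(tuple(bins), label=str(payload.get("label", "")))
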