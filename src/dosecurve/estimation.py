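"""Per-examination effective-dose estimation.

An examination record carries the patient's decimal age, the
scanner-reported DLP (mGy*cm) and optionally the effective dose
reported by a dose management system.  For each requested method the
ED is the product of the DLP and that method's conversion factor;
the device channel passes the system-reported ED through unchanged.

Curve, linear and simple factors are evaluated at the floored integer
age by default (the convention of age-resolved dose surveys); a
continuous-age switch evaluates the curve and linear methods at the
actual decimal age instead.  The phantom-bin method always uses the
actual age because its bin edges are sub-year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .anchors import AnchorTable, PhantomBinTable
from .conversion import curve_factor, linear_factor, phantom_bin_factor, simple_factor
from .exceptions import ValidationError
from .powerlaw import PowerLawModel

__all__ = [
    "METHODS",
    "DoseRecord",
    "ConversionResult",
    "estimate_ed",
    "ed_dlp_ratio",
    "convert_record",
    "convert_records",
]

#: Recognized method labels for ED estimation.
METHODS = ("curve", "linear", "simple", "phantom_bin", "device")

#: Flag set on results where the curve method was requested below 1 year
#: of age: the fitted curve changes steeply there and within-first-year
#: ED changes should not be read off it.
CURVE_FIRST_YEAR_FLAG = "curve_first_year_caution"


@dataclass(frozen=True)
class DoseRecord:
    """One CT examination: identifiers, decimal age, DLP, optional device ED."""

    exam_id: str
    age_years: float
    dlp: float
    device_ed: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if not math.isfinite(self.age_years) or self.age_years < 0:
            raise ValidationError(
                f"record {self.exam_id}: age_years must be >= 0, got {self.age_years}"
            )
        if not math.isfinite(self.dlp) or self.dlp < 0:
            raise ValidationError(
                f"record {self.exam_id}: dlp must be >= 0, got {self.dlp}"
            )
        if self.device_ed is not None and (
            not math.isfinite(self.device_ed) or self.device_ed < 0
        ):
            raise ValidationError(
                f"record {self.exam_id}: device_ed must be >= 0, got {self.device_ed}"
            )


@dataclass(frozen=True)
class ConversionResult:
    """Per-method factors and effective doses for one examination."""

    exam_id: str
    integer_age: int
    factors: dict[str, float]
    ed: dict[str, float]
    missing: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


def estimate_ed(dlp: float, factor: float) -> float:
    """Effective dose (mSv) as DLP times conversion factor."""
    if dlp < 0:
        raise ValidationError(f"dlp must be >= 0, got {dlp}")
    if not factor > 0:
        raise ValidationError(f"conversion factor must be > 0, got {factor}")
    return float(dlp) * float(factor)


def ed_dlp_ratio(ed: float, dlp: float) -> float:
    """Ratio of an effective dose to its DLP (mSv per mGy*cm)."""
    if not dlp > 0:
        raise ValidationError(f"dlp must be > 0 to form an ED/DLP ratio, got {dlp}")
    return float(ed) / float(dlp)


def convert_record(
    record: DoseRecord,
    model: PowerLawModel | None = None,
    anchors: AnchorTable | None = None,
    bins: PhantomBinTable | None = None,
    methods=("curve", "linear", "simple"),
    continuous_age: bool = False,
) -> ConversionResult:
    """Apply the requested conversion methods to one dose record.

    A requested ``device`` method with no device ED on the record is
    reported in ``missing`` rather than raising.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown method(s) {sorted(unknown)}; valid: {METHODS}")
    if "curve" in methods and model is None:
        raise ValidationError("curve method requested but no model given")
    if ("linear" in methods or "simple" in methods) and anchors is None:
        raise ValidationError("linear/simple method requested but no anchors given")
    if "phantom_bin" in methods and bins is None:
        raise ValidationError("phantom_bin method requested but no bin table given")

    integer_age = int(math.floor(record.age_years))
    eval_age = record.age_years if continuous_age else float(integer_age)

    factors: dict[str, float] = {}
    ed: dict[str, float] = {}
    missing: list[str] = []
    flags: list[str] = []

    for method in methods:
        if method == "curve":
            factors[method] = curve_factor(model, eval_age)
            if record.age_years < 1.0:
                flags.append(CURVE_FIRST_YEAR_FLAG)
        elif method == "linear":
            factors[method] = linear_factor(anchors, eval_age)
        elif method == "simple":
            factors[method] = simple_factor(anchors, integer_age)
        elif method == "phantom_bin":
            factors[method] = phantom_bin_factor(bins, record.age_years)
        elif method == "device":
            if record.device_ed is None:
                missing.append(method)
                continue
            ed[method] = float(record.device_ed)
            if record.dlp > 0:
                factors[method] = ed_dlp_ratio(record.device_ed, record.dlp)
            continue
        ed[method] = estimate_ed(record.dlp, factors[method])

    return ConversionResult(
        exam_id=record.exam_id,
        integer_age=integer_age,
        factors=factors,
        ed=ed,
        missing=tuple(missing),
        flags=tuple(flags),
    )


def convert_records(
    records,
    model: PowerLawModel | None = None,
    anchors: AnchorTable | None = None,
    bins: PhantomBinTable | None = None,
    methods=("curve", "linear", "simple"),
    continuous_age: bool = False,
) -> list[ConversionResult]:
    """Convert a sequence of records, preserving order."""
    return [
        convert_record(
            rec, model=model, anchors=anchors, bins=bins,
            methods=methods, continuous_age=continuous_age,
        )
        for rec in records
    ]
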