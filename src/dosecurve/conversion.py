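"""The four conversion-factor methods and their comparison.

Given the ICRP anchor factors at 0, 1, 5 and 10 years, a conversion
factor at any pediatric age can be obtained by

* the **curve method** -- evaluate a fitted power law ``a (x + b)^c``
  (:func:`curve_factor`);
* the **linear method** -- piecewise-linear interpolation between
  anchors, with linear extrapolation beyond the oldest anchor
  (:func:`linear_factor`);
* the **simple method** -- use the anchor factor of the nearest anchor
  age, ties broken toward the older anchor (:func:`simple_factor`);
* a **phantom-bin (device-style) method** -- a piecewise-constant
  ED/DLP ratio per phantom age bin (:func:`phantom_bin_factor`).

:func:`relative_factor` expresses any method against the curve method,
and :func:`factor_table` tabulates everything over integer ages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anchors import AnchorTable, PhantomBinTable
from .exceptions import ValidationError
from .powerlaw import PowerLawModel

__all__ = [
    "curve_factor",
    "linear_factor",
    "simple_factor",
    "phantom_bin_factor",
    "relative_factor",
    "factor_table",
]


def curve_factor(model: PowerLawModel, age: float) -> float:
    """Conversion factor from the fitted curve at ``age`` years."""
    return model.factor(age)


def linear_factor(anchors: AnchorTable, age: float) -> float:
    """Piecewise-linear conversion factor at ``age`` years.

    Interpolates between the bracketing anchors; beyond the oldest
    anchor, extrapolates the line through the final two anchors.
    Reproduces anchor values exactly at anchor ages.
    """
    age = float(age)
    if age < 0:
        raise ValidationError(f"age must be >= 0, got {age}")
    ages, factors = anchors.ages, anchors.factors
    if age < ages[0]:
        raise ValidationError(
            f"age {age} is below the first anchor age {ages[0]}"
        )
    if age <= ages[-1]:
        return float(np.interp(age, ages, factors))
    slope = (factors[-1] - factors[-2]) / (ages[-1] - ages[-2])
    return float(factors[-1] + slope * (age - ages[-1]))


def simple_factor(anchors: AnchorTable, age_integer_years: int) -> float:
    """Anchor factor of the nearest anchor age, ties toward the older anchor.

    Defined on integer ages only (floor decimal ages first).  For the
    brain anchors this reproduces the assignment 0 -> 0 y, 1-2 -> 1 y,
    3-7 -> 5 y, 8-14 -> 10 y.
    """
    age = age_integer_years
    if isinstance(age, float) and not age.is_integer():
        raise ValidationError(
            f"simple method is defined on integer ages; floor {age} first"
        )
    age = int(age)
    if age < 0:
        raise ValidationError(f"age must be >= 0, got {age}")
    ages, factors = anchors.ages, anchors.factors
    # min over (distance, -anchor age): equidistant anchors resolve to the older
    idx = min(range(len(ages)), key=lambda i: (abs(age - ages[i]), -ages[i]))
    return float(factors[idx])


def phantom_bin_factor(bins: PhantomBinTable, age: float) -> float:
    """Piecewise-constant device-style factor: the ratio of the bin holding ``age``."""
    return bins.factor_at(age)


def relative_factor(method_value: float, curve_value: float) -> float:
    """Ratio of a method's factor to the curve method's factor."""
    if not curve_value > 0:
        raise ValidationError(
            f"curve-method factor must be > 0, got {curve_value}"
        )
    return float(method_value) / float(curve_value)


def factor_table(
    model: PowerLawModel,
    anchors: AnchorTable,
    bins: PhantomBinTable | None = None,
    ages=range(15),
) -> pd.DataFrame:
    """Tabulate all methods and relative factors over integer ages.

    Returns a frame with one row per age and columns ``curve``,
    ``linear``, ``simple`` (plus ``phantom_bin`` when ``bins`` is
    given) and the relative factors ``rel_linear``/``rel_simple``
    against the curve method.
    """
    rows = []
    for age in ages:
        curve = curve_factor(model, age)
        linear = linear_factor(anchors, age)
        simple = simple_factor(anchors, int(age))
        row = {
            "age": int(age),
            "curve": curve,
            "linear": linear,
            "simple": simple,
            "rel_linear": relative_factor(linear, curve),
            "rel_simple": relative_factor(simple, curve),
        }
        if bins is not None:
            row["phantom_bin"] = phantom_bin_factor(bins, age)
        rows.append(row)
    return pd.DataFrame(rows)
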