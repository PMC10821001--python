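"""Synthetic pediatric brain-CT dose cohorts.

Real cohorts of AEC-modulated brain CT show a median DLP that rises
quickly over the first year of life (head growth) and keeps rising
slowly through adolescence, while a Monte-Carlo dose management system
reports an ED that is, per phantom age bin, a near-constant multiple of
the DLP.  The generator emulates exactly these two structures:

* mean DLP(age) = d_sat - (d_sat - d0) * exp(-rate * age) + slope * age,
  a saturating first-year rise on top of slow sustained growth, with
  multiplicative lognormal record-to-record noise of a configured CV;
* device ED = phantom-bin ratio(age) * DLP * lognormal noise.

Ages are drawn uniformly within each integer year; all randomness comes
from one seeded generator, so a config plus seed reproduces the cohort
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .anchors import PhantomBinTable, RADIMETRICS_BRAIN_BINS
from .estimation import DoseRecord
from .exceptions import ValidationError

__all__ = ["DlpGrowth", "CohortConfig", "default_config", "mean_dlp", "generate_cohort"]


@dataclass(frozen=True)
class DlpGrowth:
    """Mean-DLP growth curve parameters (mGy*cm and 1/years).

    ``d0`` is the mean DLP at birth, ``d_sat`` the plateau of the
    saturating component, ``rate`` its per-year approach rate and
    ``slope`` the sustained late growth per year.
    """

    d0: float = 300.0
    d_sat: float = 575.0
    rate: float = 1.1
    slope: float = 20.0

    def __post_init__(self):
        if not 0 < self.d0 < self.d_sat:
            raise ValidationError(
                f"need d_sat > d0 > 0, got d0={self.d0}, d_sat={self.d_sat}"
            )
        if not self.rate > 0:
            raise ValidationError(f"rate must be > 0, got {self.rate}")
        if self.slope < 0:
            raise ValidationError(f"slope must be >= 0, got {self.slope}")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort.

    ``counts_per_integer_age`` gives the number of examinations for
    each integer age 0..14; the bundled default totals 980.
    """

    counts_per_integer_age: tuple[int, ...] = (
        65, 65, 65, 65, 65, 65, 65, 65, 65, 65, 66, 66, 66, 66, 66,
    )
    dlp_growth: DlpGrowth = field(default_factory=DlpGrowth)
    dlp_noise_cv: float = 0.03
    device_bins: PhantomBinTable = RADIMETRICS_BRAIN_BINS
    device_noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts_per_integer_age)
        object.__setattr__(self, "counts_per_integer_age", counts)
        if len(counts) != 15:
            raise ValidationError(
                f"counts_per_integer_age needs 15 entries (ages 0..14), got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise ValidationError("counts must be >= 0")
        if self.dlp_noise_cv < 0 or self.device_noise_cv < 0:
            raise ValidationError("noise CVs must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(self.counts_per_integer_age)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["device_bins"] = {"label": self.device_bins.label, "bins": list(self.device_bins.bins)}
        return out


def default_config(seed: int = 0) -> CohortConfig:
    """The documented default cohort recipe (980 records)."""
    return CohortConfig(seed=seed)


def mean_dlp(growth: DlpGrowth, age) -> np.ndarray | float:
    """Mean DLP (mGy*cm) at decimal ``age`` under the growth curve."""
    age = np.asarray(age, dtype=float)
    out = (
        growth.d_sat
        - (growth.d_sat - growth.d0) * np.exp(-growth.rate * age)
        + growth.slope * age
    )
    return float(out) if out.ndim == 0 else out


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_cohort(config: CohortConfig) -> list[DoseRecord]:
    """Generate one seeded cohort of :class:`DoseRecord`.

    Records are ordered by integer age block; within a block, by draw
    order.  The same config (including seed) always yields the same
    cohort.
    """
    rng = np.random.default_rng(config.seed)
    records: list[DoseRecord] = []
    serial = 0
    for age_k, count in enumerate(config.counts_per_integer_age):
        if count == 0:
            continue
        ages = rng.uniform(age_k, age_k + 1, size=count)
        dlp = mean_dlp(config.dlp_growth, ages) * _lognormal_noise(
            rng, config.dlp_noise_cv, count
        )
        ratios = np.array([config.device_bins.factor_at(a) for a in ages])
        device = ratios * dlp * _lognormal_noise(rng, config.device_noise_cv, count)
        sexes = rng.choice(["M", "F"], size=count)
        for i in range(count):
            serial += 1
            records.append(
                DoseRecord(
                    exam_id=f"SYN{serial:05d}",
                    age_years=float(ages[i]),
                    dlp=float(dlp[i]),
                    device_ed=float(device[i]),
                    sex=str(sexes[i]),
                )
            )
    return records
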