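"""Power-law model of the age-dependent conversion factor and its fit.

The conversion factor from DLP to effective dose falls steeply during
infancy and more slowly afterwards.  A three-parameter shifted power
law

    y = a * (x + b) ** c

(with ``x`` age in years, ``a > 0``, ``b > 0`` so the curve is defined
at birth, and ``c < 0`` for a decreasing curve) captures this shape and
can be fitted through the four ICRP anchor factors by unweighted
nonlinear least squares.

Four points and three parameters make a deceptively hard fit: the SSR
surface is flat and banana-shaped in (b, c).  :func:`fit_power_law`
therefore profiles ``a`` in closed form over a (b, c) start grid --
for fixed (b, c) the optimal scale is  a = sum(y*g) / sum(g*g)  with
g = (x+b)**c -- and polishes every start with Levenberg-Marquardt,
keeping the lowest sum of squares.  This multi-start strategy makes the
result independent of initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .anchors import AnchorTable
from .exceptions import ConvergenceError, DomainError, UnderdeterminedFitError, ValidationError

__all__ = ["PowerLawModel", "FitResult", "fit_power_law"]

N_PARAMS = 3


@dataclass(frozen=True)
class PowerLawModel:
    """Constants of the shifted power law ``y = a * (x + b) ** c``.

    ``a`` is the factor at ``x + b = 1`` (mSv/mGy/cm), ``b`` an age
    offset in years (must be positive so the model is evaluable at
    age 0), ``c`` the dimensionless exponent (negative for a factor
    that decreases with age).
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValidationError(f"scale a must be > 0, got {self.a}")
        if not self.b > 0:
            raise ValidationError(
                f"age offset b must be > 0 so the model is defined at age 0, got {self.b}"
            )

    def factor(self, age):
        """Evaluate the conversion factor at ``age`` (years, >= 0)."""
        age_arr = np.asarray(age, dtype=float)
        if np.any(age_arr < 0):
            raise ValidationError(f"age must be >= 0, got {age}")
        shifted = age_arr + self.b
        if np.any(shifted <= 0):
            raise DomainError(f"age + b must be > 0, got {age} + {self.b}")
        out = self.a * shifted**self.c
        return float(out) if np.isscalar(age) or out.ndim == 0 else out

    __call__ = factor


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_power_law`.

    ``residuals`` are model minus anchor at each anchor age;
    ``residual_sd`` is ``sqrt(SSR / (n_points - n_params))``.
    """

    model: PowerLawModel
    residuals: tuple[float, ...]
    residual_sd: float
    converged: bool
    n_points: int
    n_params: int = N_PARAMS

    @property
    def ssr(self) -> float:
        return float(np.sum(np.square(self.residuals)))


def _start_grid(x: np.ndarray, y: np.ndarray, n_keep: int = 8):
    """Best profiled-``a`` starting points over a coarse (b, c) grid.

    Evaluates the profiled sum of squares on the whole grid and keeps
    the ``n_keep`` lowest cells, so the expensive local refinement only
    runs from the most promising basins.
    """
    bs = np.geomspace(0.02, 5.0, 24)
    cs = np.linspace(-2.0, -0.05, 24)
    g = (x[None, None, :] + bs[:, None, None]) ** cs[None, :, None]
    a = (g @ y) / np.einsum("ijk,ijk->ij", g, g)
    ssr = np.sum((a[:, :, None] * g - y[None, None, :]) ** 2, axis=2)
    ssr[a <= 0] = np.inf
    order = np.argsort(ssr, axis=None)[:n_keep]
    starts = []
    for flat in order:
        i, j = np.unravel_index(flat, ssr.shape)
        if np.isfinite(ssr[i, j]):
            starts.append((float(a[i, j]), float(bs[i]), float(cs[j])))
    return starts


def fit_power_law(
    anchors: AnchorTable,
    init: tuple[float, float, float] | None = None,
    tol: float = 1e-10,
) -> FitResult:
    """Fit ``y = a (x + b)^c`` to anchor factors by unweighted least squares.

    Parameters
    ----------
    anchors
        Anchor table with at least 4 entries (3 parameters require an
        overdetermined system).
    init
        Optional ``(a, b, c)`` starting triple, tried in addition to the
        built-in multi-start grid.
    tol
        Convergence tolerance on the relative change of the sum of
        squared residuals between candidate minima.

    Returns
    -------
    FitResult
        With ``model`` the global minimizer of
        ``sum((a (x_i + b)^c - y_i)^2)`` and
        ``residual_sd = sqrt(SSR / (n - 3))``.

    Raises
    ------
    UnderdeterminedFitError
        Fewer than 4 anchors.
    ConvergenceError
        No start converged; carries the best iterate seen.
    """
    n = len(anchors)
    if n < N_PARAMS + 1:
        raise UnderdeterminedFitError(
            f"power-law fit needs at least {N_PARAMS + 1} anchors "
            f"(3 parameters), got {n}"
        )
    x, y = anchors.ages, anchors.factors

    def residual_fn(params):
        a, b, c = params
        shifted = x + b
        if np.any(shifted <= 0):
            # smooth penalty steering the optimizer back into b > -min(x)
            return np.full_like(y, 1e3 * (1.0 + np.abs(shifted.min())))
        return a * shifted**c - y

    starts = list(_start_grid(x, y))
    if init is not None:
        starts.insert(0, tuple(float(v) for v in init))

    best = None
    last_iterate = None
    any_success = False
    for start in starts:
        if start[1] + x.min() <= 0:
            continue
        try:
            res = least_squares(
                residual_fn, start, method="lm",
                xtol=1e-15, ftol=min(tol, 1e-12), gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:  # singular Jacobian on a pathological start
            continue
        last_iterate = tuple(res.x)
        if not np.all(np.isfinite(res.x)):
            continue
        a, b, c = res.x
        if a <= 0 or b + x.min() <= 0:
            continue
        any_success = any_success or res.status > 0
        ssr = float(2.0 * res.cost)
        if best is None or ssr < best[0]:
            best = (ssr, (float(a), float(b), float(c)), res.status > 0)

    if best is None or not any_success:
        raise ConvergenceError(
            "power-law fit did not converge from any starting point",
            last_iterate=last_iterate,
        )

    ssr, (a, b, c), converged = best
    model = PowerLawModel(a=a, b=b, c=c)
    residuals = tuple(float(r) for r in (model.factor(x) - y))
    residual_sd = float(np.sqrt(ssr / (n - N_PARAMS)))
    return FitResult(
        model=model,
        residuals=residuals,
        residual_sd=residual_sd,
        converged=converged,
        n_points=n,
    )
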