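"""Per-specimen least-squares fits of the lateral-wall course.

Two competing radius models are fitted to the sampled modiolar distance
r(α):

* a logarithmic spiral  r(α) = a0 · exp(a1 · α), fitted by ordinary least
  squares on the linearised form  log r = log a0 + a1 · α  (residuals are
  minimised in log space; model-space residuals in mm are reported alongside
  for comparability), and
* a cubic polynomial spiral  r(α) = b0 + b1·α + b2·α² + b3·α³.

The axial height h(α) is fitted with a quartic polynomial.  Polynomial
solves go through :class:`numpy.polynomial.Polynomial` (QR on a scaled
domain) because α spans ~0–18 rad and raw normal equations are
ill-conditioned at degree 4; coefficients are reported in the raw
{1, α, α², …} basis in radians.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from numpy.polynomial import Polynomial

from .data import HeightProfile, RadiusProfile
from .errors import DomainError, UnderdeterminedError

__all__ = [
    "LogSpiralCoefficients",
    "PolySpiralCoefficients",
    "HeightPolyCoefficients",
    "FitResult",
    "fit_log_radius",
    "fit_poly_radius",
    "fit_height_poly",
    "eval_model",
]


@dataclass(frozen=True)
class LogSpiralCoefficients:
    """Logarithmic spiral r = a0·exp(a1·α); a0 in mm, a1 per radian."""

    a0: float
    a1: float

    model = "logarithmic"

    def __post_init__(self):
        if not self.a0 > 0:
            raise DomainError(f"log-spiral a0 must be > 0, got {self.a0}")

    def __call__(self, alpha):
        return self.a0 * np.exp(self.a1 * np.asarray(alpha, dtype=float))

    def derivative(self, alpha):
        """dr/dα in mm per radian."""
        return self.a1 * self(alpha)

    def as_array(self) -> np.ndarray:
        """(log a0, a1) — the linear-model coefficient vector."""
        return np.array([math.log(self.a0), self.a1])


@dataclass(frozen=True)
class PolySpiralCoefficients:
    """Cubic radius polynomial r = b0 + b1·α + b2·α² + b3·α³ (mm, α in rad)."""

    b0: float
    b1: float
    b2: float
    b3: float

    model = "polynomial"

    def __call__(self, alpha):
        return np.polynomial.polynomial.polyval(np.asarray(alpha, dtype=float), self.as_array())

    def derivative(self, alpha):
        a = np.asarray(alpha, dtype=float)
        return self.b1 + 2 * self.b2 * a + 3 * self.b3 * a * a

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3])


@dataclass(frozen=True)
class HeightPolyCoefficients:
    """Quartic height polynomial h = c0 + c1·α + … + c4·α⁴ (mm, α in rad)."""

    c0: float
    c1: float
    c2: float
    c3: float
    c4: float

    model = "height"

    def __call__(self, alpha):
        return np.polynomial.polynomial.polyval(np.asarray(alpha, dtype=float), self.as_array())

    def derivative(self, alpha):
        a = np.asarray(alpha, dtype=float)
        return self.c1 + 2 * self.c2 * a + 3 * self.c3 * a * a + 4 * self.c4 * a ** 3

    def as_array(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2, self.c3, self.c4])


Coefficients = Union[LogSpiralCoefficients, PolySpiralCoefficients, HeightPolyCoefficients]


@dataclass(frozen=True)
class FitResult:
    """A least-squares fit: coefficients plus model-space residuals (mm).

    ``residuals`` are data − model at the sample points; ``sum_sq_residuals``
    is their sum of squares.  For the logarithmic fit, the value of the
    actually-minimised objective (sum of squared log-space residuals) is kept
    in ``log_space_ssr``.
    """

    coefficients: Coefficients
    residuals: np.ndarray
    sum_sq_residuals: float
    n_samples: int
    log_space_ssr: float | None = None

    def to_json(self) -> str:
        doc = {
            "model": self.coefficients.model,
            "coefficients": (
                [self.coefficients.a0, self.coefficients.a1]
                if isinstance(self.coefficients, LogSpiralCoefficients)
                else self.coefficients.as_array().tolist()
            ),
            "angle_unit": "radians",
            "sum_sq_residuals_mm2": self.sum_sq_residuals,
            "n_samples": self.n_samples,
        }
        if self.log_space_ssr is not None:
            doc["log_space_ssr"] = self.log_space_ssr
        return json.dumps(doc, indent=2)


def _prepare(alpha: np.ndarray, y: np.ndarray, min_distinct: int, what: str):
    alpha = np.asarray(alpha, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(y) & np.isfinite(alpha)
    alpha, y = alpha[m], y[m]
    if np.unique(alpha).size < min_distinct:
        raise UnderdeterminedError(
            f"{what}: needs at least {min_distinct} distinct angular positions, "
            f"got {np.unique(alpha).size}"
        )
    return alpha, y


def _polyfit_raw(alpha: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Least squares on {1, α, …, α^degree}, solved on a scaled domain for
    conditioning, returned in the raw basis."""
    p = Polynomial.fit(alpha, y, deg=degree)
    coef = p.convert().coef
    if coef.size < degree + 1:  # numpy trims exact trailing zeros
        coef = np.pad(coef, (0, degree + 1 - coef.size))
    return coef


def fit_log_radius(profile: RadiusProfile) -> FitResult:
    """Fit the logarithmic spiral by OLS on (α, log r).

    Raises :class:`DomainError` if any present radius is ≤ 0 and
    :class:`UnderdeterminedError` with fewer than 2 distinct angles.
    """
    alpha, r = _prepare(profile.alpha, profile.r, 2, "logarithmic radius fit")
    if np.any(r <= 0):
        raise DomainError("logarithmic fit: all radii must be > 0")
    logc = _polyfit_raw(alpha, np.log(r), 1)
    coeffs = LogSpiralCoefficients(a0=float(np.exp(logc[0])), a1=float(logc[1]))
    resid = r - coeffs(alpha)
    log_resid = np.log(r) - (logc[0] + logc[1] * alpha)
    return FitResult(
        coefficients=coeffs,
        residuals=resid,
        sum_sq_residuals=float(resid @ resid),
        n_samples=int(r.size),
        log_space_ssr=float(log_resid @ log_resid),
    )


def fit_poly_radius(profile: RadiusProfile) -> FitResult:
    """Fit the cubic polynomial spiral by OLS on {1, α, α², α³}."""
    alpha, r = _prepare(profile.alpha, profile.r, 4, "polynomial radius fit")
    coef = _polyfit_raw(alpha, r, 3)
    coeffs = PolySpiralCoefficients(*coef.tolist())
    resid = r - coeffs(alpha)
    return FitResult(coeffs, resid, float(resid @ resid), int(r.size))


def fit_height_poly(profile: HeightProfile) -> FitResult:
    """Fit the quartic height polynomial by OLS on {1, α, …, α⁴}."""
    alpha, h = _prepare(profile.alpha, profile.h, 5, "height fit")
    coef = _polyfit_raw(alpha, h, 4)
    coeffs = HeightPolyCoefficients(*coef.tolist())
    resid = h - coeffs(alpha)
    return FitResult(coeffs, resid, float(resid @ resid), int(h.size))


def eval_model(coefficients: Coefficients, alpha):
    """Evaluate a fitted radius or height model at angular position(s) α (rad)."""
    return coefficients(alpha)
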