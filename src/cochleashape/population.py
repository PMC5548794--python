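"""Population-level prediction of the 3D cochlear curve.

Each per-specimen model coefficient (radius, height, angular length) is
regressed by ordinary least squares on the five predictors
(1, A_a, B_a, A_b, B_b) — the modiolar cuts of the two base axes plus an
intercept.  Because the regressions are separable, the trained model is a
set of coefficient matrices:

* ``M`` — predictors × radius-coefficients (5×4 cubic, or 5×2 for the
  logarithmic spiral, whose linear coefficients are (log a0, a1)),
* ``H`` — predictors × height-coefficients (5×5 quartic),
* ``M_deg`` — predictors × angular length, regressed in **turns** and
  converted to degrees only at the interface.

A predicted cochlea is the parametric 3D curve

    x(α) = cos(α)·r̂(α),  y(α) = ±sin(α)·r̂(α),  z(α) = ĥ(α)

on α ∈ [0, angular length] (left-handed canonical chirality: +sin).  Its
metric (lateral-wall) length is the arc length ∫‖(x,y,z)'(α)‖ dα, computed
by adaptive quadrature; basilar-membrane length is approximated as 87 % of
the lateral-wall length.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .data import BaseParameters, PopulationTable, PREDICTOR_NAMES
from .errors import CochleaError, DomainError, ImplausiblePredictionWarning, UnderdeterminedError
from .fitting import (
    HeightPolyCoefficients,
    LogSpiralCoefficients,
    PolySpiralCoefficients,
    fit_height_poly,
    fit_log_radius,
    fit_poly_radius,
)

__all__ = [
    "PredictionModel",
    "PredictedCochlea",
    "train",
    "predict",
    "arc_length",
    "metric_length",
    "basilar_membrane_length",
    "curve_to_csv",
    "curve_to_obj",
]

#: Fraction of the lateral-wall length covered by the basilar membrane.
BASILAR_MEMBRANE_FRACTION = 0.87

#: Absolute quadrature tolerance for arc lengths (mm).
ARC_LENGTH_ABS_TOL = 1e-8


@dataclass(frozen=True)
class PredictionModel:
    """Coefficient-prediction matrices over predictors (1, A_a, B_a, A_b, B_b).

    ``M`` maps predictors to radius coefficients (columns are powers α⁰..α³
    for the polynomial model, or (log a0, a1) for the logarithmic model),
    ``H`` to height coefficients α⁰..α⁴, and ``M_deg`` to the angular length
    in turns.
    """

    radius_model: str  # "polynomial" | "logarithmic"
    M: np.ndarray  # (5, 4) or (5, 2)
    H: np.ndarray  # (5, 5)
    M_deg: np.ndarray  # (5,)
    training_n: int

    def __post_init__(self):
        if self.radius_model not in ("polynomial", "logarithmic"):
            raise CochleaError(f"unknown radius model {self.radius_model!r}")
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float))
        object.__setattr__(self, "H", np.asarray(self.H, dtype=float))
        object.__setattr__(self, "M_deg", np.asarray(self.M_deg, dtype=float).reshape(5))
        k = 4 if self.radius_model == "polynomial" else 2
        if self.M.shape != (5, k) or self.H.shape != (5, 5):
            raise CochleaError("coefficient matrix shape mismatch")
        if self.training_n < 5:
            raise UnderdeterminedError("prediction model needs training_n >= 5")

    def to_json(self) -> str:
        return json.dumps(
            {
                "predictor_order": list(PREDICTOR_NAMES),
                "radius_model": self.radius_model,
                "M": self.M.tolist(),
                "H": self.H.tolist(),
                "M_deg": self.M_deg.tolist(),
                "angular_length_unit": "turns",
                "angle_unit": "radians",
                "training_n": self.training_n,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PredictionModel":
        doc = json.loads(text)
        return cls(
            radius_model=doc["radius_model"],
            M=np.array(doc["M"]),
            H=np.array(doc["H"]),
            M_deg=np.array(doc["M_deg"]),
            training_n=int(doc["training_n"]),
        )


@dataclass(frozen=True)
class PredictedCochlea:
    """A parametric 3D cochlear curve predicted from four base measures.

    ``curve(α)`` returns stacked (x, y, z) in mm for α in radians on
    [0, angular length]; ``plausible`` is False when the predicted radius
    dips non-positive or the angular length does not exceed one turn.
    """

    base: BaseParameters
    radius_coeffs: PolySpiralCoefficients | LogSpiralCoefficients
    height_coeffs: HeightPolyCoefficients
    angular_length: float  # degrees
    chirality: str = "left"
    plausible: bool = True

    @property
    def angular_length_rad(self) -> float:
        return math.radians(self.angular_length)

    @property
    def angular_length_turns(self) -> float:
        return self.angular_length / 360.0

    def radius(self, alpha):
        return self.radius_coeffs(alpha)

    def height(self, alpha):
        return self.height_coeffs(alpha)

    def curve(self, alpha):
        """Cartesian (x, y, z) at α (radians); shape (..., 3)."""
        a = np.asarray(alpha, dtype=float)
        r = self.radius_coeffs(a)
        sign = 1.0 if self.chirality == "left" else -1.0
        return np.stack([np.cos(a) * r, sign * np.sin(a) * r, self.height_coeffs(a)], axis=-1)


def _specimen_coefficients(population: PopulationTable, radius_model: str):
    fit_radius = fit_poly_radius if radius_model == "polynomial" else fit_log_radius
    rows_r, rows_h, l_turns, failures = [], [], [], []
    for rec in population:
        try:
            rows_r.append(fit_radius(rec.radius).coefficients.as_array())
            rows_h.append(fit_height_poly(rec.height).coefficients.as_array())
        except CochleaError as exc:
            failures.append(f"{rec.id}: {exc}")
            continue
        l_turns.append(rec.angular_length / 360.0)
    if failures:
        raise CochleaError("individual fits failed for specimen(s): " + "; ".join(failures))
    return np.array(rows_r), np.array(rows_h), np.array(l_turns)


def _design(population: PopulationTable) -> np.ndarray:
    return np.array([rec.base.predictor_vector() for rec in population])


def train(population: PopulationTable, radius_model: str = "polynomial") -> PredictionModel:
    """Train the coefficient-prediction model on a measured population.

    Per-specimen radius/height fits are computed first; every resulting
    coefficient (and the angular length, in turns) is then regressed
    independently on (1, A_a, B_a, A_b, B_b).

    Raises :class:`UnderdeterminedError` for fewer than 5 records and
    :class:`CochleaError` naming the collinear predictors when the design
    matrix is rank-deficient, or listing specimens whose individual fit
    failed.
    """
    if radius_model not in ("polynomial", "logarithmic"):
        raise CochleaError(f"unknown radius model {radius_model!r}")
    if len(population) < 5:
        raise UnderdeterminedError(
            f"training needs at least 5 records (one per predictor), got {len(population)}"
        )
    X = _design(population)
    if np.linalg.matrix_rank(X) < 5:
        # identify offending columns via the rank increase when added one by one
        collinear = []
        for j in range(1, 5):
            sub = X[:, [k for k in range(5) if k != j]]
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                collinear.append(PREDICTOR_NAMES[j])
        raise CochleaError(
            "rank-deficient predictor design; collinear predictor(s): "
            + (", ".join(collinear) or "unidentified")
        )
    R, Hc, l_turns = _specimen_coefficients(population, radius_model)
    M, *_ = np.linalg.lstsq(X, R, rcond=None)
    H, *_ = np.linalg.lstsq(X, Hc, rcond=None)
    M_deg, *_ = np.linalg.lstsq(X, l_turns, rcond=None)
    return PredictionModel(radius_model=radius_model, M=M, H=H, M_deg=M_deg, training_n=len(population))


def predict(model: PredictionModel, base: BaseParameters, chirality: str = "left") -> PredictedCochlea:
    """Predict the full 3D cochlear curve from the four base parameters.

    Implausible outcomes (predicted angular length ≤ 360° or a non-positive
    radius anywhere on the domain) are returned flagged ``plausible=False``
    with an :class:`ImplausiblePredictionWarning` — never clamped, so
    validation residuals stay unbiased.
    """
    theta = base.predictor_vector()
    rc = theta @ model.M
    if model.radius_model == "polynomial":
        radius_coeffs = PolySpiralCoefficients(*rc.tolist())
    else:
        radius_coeffs = LogSpiralCoefficients(a0=float(np.exp(rc[0])), a1=float(rc[1]))
    height_coeffs = HeightPolyCoefficients(*(theta @ model.H).tolist())
    l_deg = float(theta @ model.M_deg) * 360.0

    plausible = l_deg > 360.0
    if plausible:
        grid = np.linspace(0.0, math.radians(l_deg), 512)
        plausible = bool(np.all(radius_coeffs(grid) > 0))
    if not plausible:
        warnings.warn(
            f"implausible prediction for base {base}: angular length {l_deg:.1f} deg "
            "or non-positive radius on the domain",
            ImplausiblePredictionWarning,
            stacklevel=2,
        )
    return PredictedCochlea(
        base=base,
        radius_coeffs=radius_coeffs,
        height_coeffs=height_coeffs,
        angular_length=l_deg,
        chirality=chirality,
        plausible=plausible,
    )


def arc_length(
    pred: PredictedCochlea,
    alpha_from: float = 0.0,
    alpha_to: float | None = None,
    include_height: bool = True,
) -> float:
    """Arc length (mm) of the predicted curve between two angles (radians).

    The speed ‖d(x,y,z)/dα‖ = sqrt(r'² + r² + h'²) is integrated with
    adaptive quadrature (absolute tolerance ``ARC_LENGTH_ABS_TOL``).  With
    ``include_height=False`` the height is held constant, giving the planar
    length used in the with/without-height comparison.
    """
    if alpha_to is None:
        alpha_to = pred.angular_length_rad
    if not alpha_from < alpha_to:
        raise DomainError(f"inverted integration range [{alpha_from}, {alpha_to}]")
    r, h = pred.radius_coeffs, pred.height_coeffs

    def speed(a):
        rr = r(a)
        dr = r.derivative(a)
        s = rr * rr + dr * dr
        if include_height:
            dh = h.derivative(a)
            s = s + dh * dh
        return np.sqrt(s)

    # subdivide per turn so the adaptive rule tracks the oscillation-free but
    # long domain without exhausting its interval budget
    n_seg = max(1, int(math.ceil((alpha_to - alpha_from) / (2 * math.pi))))
    edges = np.linspace(alpha_from, alpha_to, n_seg + 1)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(speed, lo, hi, epsabs=ARC_LENGTH_ABS_TOL, epsrel=1e-10, limit=200)
        total += val
    return total


def metric_length(pred: PredictedCochlea, include_height: bool = True) -> float:
    """Lateral-wall length (mm): arc length over the full angular domain."""
    return arc_length(pred, 0.0, pred.angular_length_rad, include_height=include_height)


def basilar_membrane_length(lateral_wall_length: float) -> float:
    """Basilar-membrane length approximated as 87 % of the lateral-wall length."""
    if not lateral_wall_length > 0:
        raise DomainError(f"lateral wall length must be > 0, got {lateral_wall_length}")
    return BASILAR_MEMBRANE_FRACTION * lateral_wall_length


def curve_to_csv(pred: PredictedCochlea, path, step_deg: float = 5.0) -> None:
    """Export the predicted curve as an (alpha_deg, x, y, z) CSV polyline."""
    n = max(2, int(round(pred.angular_length / step_deg)) + 1)
    a_deg = np.linspace(0.0, pred.angular_length, n)
    xyz = pred.curve(np.radians(a_deg))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# predicted cochlear lateral-wall curve; units mm, angles degrees\n")
        fh.write(f"# chirality: {pred.chirality}; angular length {pred.angular_length!r} deg\n")
        fh.write("alpha_deg,x_mm,y_mm,z_mm\n")
        for a, (x, y, z) in zip(a_deg, xyz):
            fh.write(f"{float(a)!r},{float(x)!r},{float(y)!r},{float(z)!r}\n")


def curve_to_obj(pred: PredictedCochlea, path, step_deg: float = 5.0) -> None:
    """Export the predicted curve as a Wavefront OBJ polyline for 3D viewers."""
    n = max(2, int(round(pred.angular_length / step_deg)) + 1)
    xyz = pred.curve(np.radians(np.linspace(0.0, pred.angular_length, n)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cochleashape predicted lateral-wall polyline (mm)\n")
        for x, y, z in xyz:
            fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
        fh.write("l " + " ".join(str(i + 1) for i in range(n)) + "\n")
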