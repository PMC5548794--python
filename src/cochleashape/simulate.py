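"""Seeded generator of virtual cochlear populations with known ground truth.

The generator emulates the statistical structure of an adult human
population: the four base parameters (A_a, A_b, B_a, B_b) are drawn from a
multivariate normal (rejection-resampled to positivity), and every
per-specimen model coefficient follows the same linear law the prediction
model assumes —

    coefficient = (1, A_a, B_a, A_b, B_b) · true matrix

— so parameter recovery and pipeline closure are well-posed tests.  Radius
and height samples are taken on a regular angular grid up to each record's
own angular length (samples beyond it are absent, as in real measurement
tables) with independent Gaussian noise.

The default configuration is calibrated to the published population
envelopes: lateral-wall metric lengths of roughly 36–46 mm, an angular
length spread of ≈200° across a ~100-specimen study, and a radii ratio of
7.57 ± 1.51.  Two couplings shape the defaults:

* ``rollercoaster_coupling`` — strength with which B-axis asymmetry
  (B_b − B_a) deepens a first-turn dip of the vertical profile;
* ``wrapping_area_coupling`` — (negative) dependence of the angular length
  on overall base size, which makes tight wrapping co-occur with small
  cochlear bases.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .data import BaseParameters, CochleaRecord, HeightProfile, PopulationTable, RadiusProfile
from .errors import ValidationError
from .fitting import HeightPolyCoefficients, LogSpiralCoefficients, PolySpiralCoefficients
from .population import PredictedCochlea, metric_length

__all__ = ["GeneratorConfig", "SyntheticPopulation", "default_config", "generate"]

# ---------------------------------------------------------------------------
# anchor quantities for the default population (see docs/methods.md)

_BASE_MEAN = np.array([5.3, 3.7, 3.5, 3.3])  # (A_a, A_b, B_a, B_b) mm
_BASE_SD = np.array([0.45, 0.35, 0.30, 0.30])
_BASE_CORR = 0.4

_L_REF_TURNS = 2.45  # reference angular length, turns
_TURNS_BOUNDS = (2.05, 2.95)  # records outside are redrawn (radius positivity)

# radius law anchors (typical specimen): starting radius at the round window,
# mean radius over the apical 90° window, the integral of r over the domain
# (sets the metric length scale) and the end slope (sets how strongly the
# apex radius depends on angular length)
_R_START = 5.4  # mm
_R_APEX_WINDOW = 0.632  # mm
_R_INTEGRAL = 40.5  # mm·rad over [0, L_ref]
_R_END_SLOPE = -0.04  # mm/rad

# dependence of the radius scale b0 on A_a and B_a, mm per mm
_B0_SENSITIVITY = 0.17
# small dependencies of the higher radius coefficients on the "b" segments
_B1_ON_AB = 0.004
_B2_ON_BB = 0.0005

# height law anchors: quadratic ascent reaching _H_APEX at the reference
# apex, and a unit dip shape bottoming at 270°, vanishing at the reference
# apex
_H_APEX = 2.4  # mm
_DIP_MIN_RAD = 1.5 * math.pi  # 270 deg
_DIP_BASELINE = 0.5  # mean dip amplitude, mm at unit coupling


def _solve_default_radius_law(l_ref: float) -> np.ndarray:
    """Cubic b solving: r(0)=R_START, apex-window mean = R_APEX_WINDOW,
    ∫r = R_INTEGRAL, r'(l_ref) = R_END_SLOPE.  All conditions linear in b."""
    lo = l_ref - math.pi / 2.0

    def int_row(a, b_):  # ∫ alpha^k over [a,b] for k=0..3
        return np.array([(b_ ** (k + 1) - a ** (k + 1)) / (k + 1) for k in range(4)])

    A = np.vstack(
        [
            [1.0, 0.0, 0.0, 0.0],
            int_row(lo, l_ref) / (math.pi / 2.0),
            int_row(0.0, l_ref),
            [0.0, 1.0, 2.0 * l_ref, 3.0 * l_ref ** 2],
        ]
    )
    rhs = np.array([_R_START, _R_APEX_WINDOW, _R_INTEGRAL, _R_END_SLOPE])
    return np.linalg.solve(A, rhs)


def _solve_default_dip_shape(l_ref: float) -> np.ndarray:
    """Quartic dip D (D(0)=0) with unit depth and zero slope at 270°, and
    vanishing value and slope at the reference apex."""
    m = _DIP_MIN_RAD

    def row(a, ks=range(1, 5)):
        return np.array([a ** k for k in ks])

    A = np.vstack(
        [
            row(m),
            [k * m ** (k - 1) for k in range(1, 5)],  # D'(min) = 0
            row(l_ref),
            [k * l_ref ** (k - 1) for k in range(1, 5)],  # D'(apex) = 0
        ]
    )
    d = np.linalg.solve(A, np.array([-1.0, 0.0, 0.0, 0.0]))
    return np.concatenate([[0.0], d])


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cochlear population.

    ``true_M_pol`` (5×4), ``true_H_pol`` (5×5) and ``true_M_deg`` (5,) are
    the generating coefficient matrices over predictors
    (1, A_a, B_a, A_b, B_b); the angular length law is in turns.  With
    ``radius_law="logarithmic"`` the radius instead follows
    r = exp(θ·true_M_log·(1, α)), a deliberate misspecification mode.
    """

    n: int
    seed: int
    base_mean: np.ndarray
    base_cov: np.ndarray
    true_M_pol: np.ndarray
    true_H_pol: np.ndarray
    true_M_deg: np.ndarray
    radius_noise_sd: float = 0.05
    height_noise_sd: float = 0.1
    angular_sampling_step: float = 90.0  # degrees
    rollercoaster_coupling: float = 1.0
    wrapping_area_coupling: float = -0.10
    radius_law: str = "cubic"
    true_M_log: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "base_mean", np.asarray(self.base_mean, dtype=float).reshape(4))
        object.__setattr__(self, "base_cov", np.asarray(self.base_cov, dtype=float).reshape(4, 4))
        object.__setattr__(self, "true_M_pol", np.asarray(self.true_M_pol, dtype=float).reshape(5, 4))
        object.__setattr__(self, "true_H_pol", np.asarray(self.true_H_pol, dtype=float).reshape(5, 5))
        object.__setattr__(self, "true_M_deg", np.asarray(self.true_M_deg, dtype=float).reshape(5))
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if self.radius_noise_sd < 0 or self.height_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if not np.allclose(self.base_cov, self.base_cov.T):
            raise ValidationError("base covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.base_cov) <= 0):
            raise ValidationError("base covariance must be positive definite")
        if not self.angular_sampling_step > 0:
            raise ValidationError("angular sampling step must be > 0")
        if self.radius_law not in ("cubic", "logarithmic"):
            raise ValidationError(f"unknown radius law {self.radius_law!r}")
        if self.radius_law == "logarithmic":
            if self.true_M_log is None:
                raise ValidationError("logarithmic radius law needs true_M_log")
            object.__setattr__(self, "true_M_log", np.asarray(self.true_M_log, dtype=float).reshape(5, 2))


@dataclass(frozen=True)
class SyntheticPopulation:
    """A generated population plus its exact ground truth."""

    table: PopulationTable
    config: GeneratorConfig
    true_radius_coeffs: dict  # id -> np.ndarray
    true_height_coeffs: dict  # id -> np.ndarray
    true_angular_length_turns: dict  # id -> float

    def ground_truth_json(self) -> str:
        return json.dumps(
            {
                "seed": self.config.seed,
                "radius_law": self.config.radius_law,
                "true_M_pol": self.config.true_M_pol.tolist(),
                "true_H_pol": self.config.true_H_pol.tolist(),
                "true_M_deg": self.config.true_M_deg.tolist(),
                "records": {
                    rid: {
                        "radius_coeffs": self.true_radius_coeffs[rid].tolist(),
                        "height_coeffs": self.true_height_coeffs[rid].tolist(),
                        "angular_length_turns": self.true_angular_length_turns[rid],
                    }
                    for rid in self.true_radius_coeffs
                },
            },
            indent=2,
        )


def default_config(
    n: int = 108,
    seed: int = 0,
    radius_noise_sd: float = 0.05,
    height_noise_sd: float = 0.1,
    angular_sampling_step: float = 90.0,
    rollercoaster_coupling: float = 1.0,
    wrapping_area_coupling: float = -0.10,
) -> GeneratorConfig:
    """The calibrated default population (see module docstring).

    The generating matrices are assembled from the documented anchor
    quantities: the radius cubic is solved from its boundary conditions, the
    height law is a quadratic ascent plus an asymmetry-coupled dip, and the
    angular length decreases with overall base size at
    ``wrapping_area_coupling`` turns per mm.
    """
    l_ref = _L_REF_TURNS * 2.0 * math.pi
    mu = _BASE_MEAN

    b_star = _solve_default_radius_law(l_ref)
    M_pol = np.zeros((5, 4))
    # b0 scales with A_a and B_a (predictor rows 1 and 2 in package order)
    M_pol[0, 0] = b_star[0] - _B0_SENSITIVITY * (mu[0] + mu[2])
    M_pol[1, 0] = _B0_SENSITIVITY
    M_pol[2, 0] = _B0_SENSITIVITY
    # mild dependencies of the higher coefficients
    M_pol[0, 1] = b_star[1] - _B1_ON_AB * mu[1]
    M_pol[3, 1] = _B1_ON_AB
    M_pol[0, 2] = b_star[2] - _B2_ON_BB * mu[3]
    M_pol[4, 2] = _B2_ON_BB
    M_pol[0, 3] = b_star[3]

    # height: quadratic ascent to _H_APEX at the reference apex ...
    H = np.zeros((5, 5))
    H[0, 2] = _H_APEX / l_ref ** 2
    # ... plus the dip, coupled to B-axis asymmetry (B_b - B_a)
    dip = _solve_default_dip_shape(l_ref)
    lam = rollercoaster_coupling
    H[0] += lam * _DIP_BASELINE * dip
    H[2] -= lam * dip  # B_a row
    H[4] += lam * dip  # B_b row

    # angular length in turns, decreasing with overall base size
    kappa = wrapping_area_coupling
    M_deg = np.array([_L_REF_TURNS - kappa * mu.sum(), kappa, kappa, kappa, kappa])

    cov = np.outer(_BASE_SD, _BASE_SD) * (
        np.full((4, 4), _BASE_CORR) + (1.0 - _BASE_CORR) * np.eye(4)
    )
    return GeneratorConfig(
        n=n,
        seed=seed,
        base_mean=mu.copy(),
        base_cov=cov,
        true_M_pol=M_pol,
        true_H_pol=H,
        true_M_deg=M_deg,
        radius_noise_sd=radius_noise_sd,
        height_noise_sd=height_noise_sd,
        angular_sampling_step=angular_sampling_step,
        rollercoaster_coupling=rollercoaster_coupling,
        wrapping_area_coupling=wrapping_area_coupling,
    )


def _draw_specimen(rng: np.random.Generator, cfg: GeneratorConfig):
    """Draw one specimen's base parameters, angular length and true models.

    Rejection-resamples until the base parameters are positive, the angular
    length is anatomically plausible and the true radius law is strictly
    positive over the specimen's whole domain."""
    for _ in range(10000):
        b = rng.multivariate_normal(cfg.base_mean, cfg.base_cov)
        if np.any(b <= 0):
            continue
        theta = np.array([1.0, b[0], b[2], b[1], b[3]])  # (1, A_a, B_a, A_b, B_b)
        l_turns = float(theta @ cfg.true_M_deg)
        if not (_TURNS_BOUNDS[0] <= l_turns <= _TURNS_BOUNDS[1]):
            continue
        if cfg.radius_law == "cubic":
            r_coef = theta @ cfg.true_M_pol
            radius_model = PolySpiralCoefficients(*r_coef.tolist())
        else:
            r_coef = theta @ cfg.true_M_log
            radius_model = LogSpiralCoefficients(a0=float(np.exp(r_coef[0])), a1=float(r_coef[1]))
        dense = np.linspace(0.0, l_turns * 2.0 * math.pi, 256)
        if np.any(radius_model(dense) <= 0):
            continue
        return b, theta, l_turns, r_coef, radius_model
    raise ValidationError("could not draw a plausible specimen in 10000 attempts; check config")


def generate(config: GeneratorConfig) -> SyntheticPopulation:
    """Generate a synthetic population; identical configs are bitwise
    reproducible (single seeded ``numpy.random.default_rng`` stream)."""
    rng = np.random.default_rng(config.seed)
    step_rad = math.radians(config.angular_sampling_step)
    records = []
    true_r, true_h, true_l = {}, {}, {}

    for i in range(config.n):
        b, theta, l_turns, r_coef, radius_model = _draw_specimen(rng, config)
        rid = f"S{i:04d}"
        base = BaseParameters(A_a=b[0], A_b=b[1], B_a=b[2], B_b=b[3])
        l_rad = l_turns * 2.0 * math.pi

        h_coef = theta @ config.true_H_pol
        height_model = HeightPolyCoefficients(*h_coef.tolist())

        n_samples = int(math.floor(l_rad / step_rad + 1e-9)) + 1
        alpha = np.arange(n_samples) * step_rad
        r_true = radius_model(alpha)
        r_obs = r_true + rng.normal(0.0, config.radius_noise_sd, size=n_samples)
        for _ in range(100):  # keep observed radii positive (measurement can't be <= 0)
            bad = r_obs <= 0
            if not bad.any():
                break
            r_obs[bad] = r_true[bad] + rng.normal(0.0, config.radius_noise_sd, size=int(bad.sum()))
        h_obs = height_model(alpha) + rng.normal(0.0, config.height_noise_sd, size=n_samples)

        pred = PredictedCochlea(
            base=base,
            radius_coeffs=radius_model,
            height_coeffs=height_model,
            angular_length=l_turns * 360.0,
        )
        metric = metric_length(pred)

        records.append(
            CochleaRecord(
                id=rid,
                side="left" if rng.random() < 0.55 else "right",
                base=base,
                radius=RadiusProfile(alpha=alpha, r=r_obs),
                height=HeightProfile(alpha=alpha, h=h_obs),
                angular_length=l_turns * 360.0,
                metric_length_measured=metric,
            )
        )
        true_r[rid] = r_coef
        true_h[rid] = h_coef
        true_l[rid] = l_turns

    return SyntheticPopulation(
        table=PopulationTable(records),
        config=config,
        true_radius_coeffs=true_r,
        true_height_coeffs=true_h,
        true_angular_length_turns=true_l,
    )
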