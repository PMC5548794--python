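"""Node-wise residual evaluation, leave-one-out cross-validation and paired
model comparison.

Prediction quality is scored at equidistant 90° nodes of the angular
length: at each node the measured modiolar distance (and height) is
compared with the model prediction.  Measured node values come from linear
interpolation of the sampled profile when no sample falls exactly on a
node; nodes beyond a specimen's own angular length are simply absent (no
imputation), matching how shorter cochleae carry fewer measurement points.

Two radius models are compared by summing squared node residuals per
specimen and testing the paired differences (two-sided paired t and
Wilcoxon signed-rank, α = 0.05, no multiplicity correction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import CochleaRecord, PopulationTable
from .errors import CochleaError, UnderdeterminedError, ValidationError
from .population import PredictedCochlea, PredictionModel, metric_length, predict, train

__all__ = [
    "NodeResiduals",
    "ComparisonReport",
    "node_residuals",
    "loocv",
    "loocv_summary",
    "compare_models",
]

NODE_STEP_DEG = 90.0


@dataclass(frozen=True)
class NodeResiduals:
    """Measured − predicted residuals for one specimen.

    ``radius_residuals`` / ``height_residuals`` (mm) align with
    ``node_angles_deg`` (multiples of 90° within the specimen's angular
    length); absent measurements are NaN, never zero.
    ``angular_length_residual`` is in turns; ``metric_length_residual`` (mm)
    is NaN when the specimen has no independently measured length.
    """

    specimen_id: str
    node_angles_deg: np.ndarray
    radius_residuals: np.ndarray
    height_residuals: np.ndarray
    angular_length_residual: float
    metric_length_residual: float

    def ssr(self, quantity: str = "radius") -> float:
        """Sum of squared node residuals (mm²) over available nodes."""
        v = {"radius": self.radius_residuals, "height": self.height_residuals}[quantity]
        v = v[np.isfinite(v)]
        return float(v @ v)

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "node_angles_deg": self.node_angles_deg.tolist(),
            "radius_residuals_mm": [None if not np.isfinite(x) else x for x in self.radius_residuals],
            "height_residuals_mm": [None if not np.isfinite(x) else x for x in self.height_residuals],
            "angular_length_residual_turns": self.angular_length_residual,
            "metric_length_residual_mm": (
                None if not np.isfinite(self.metric_length_residual) else self.metric_length_residual
            ),
        }


def _interp_nodes(alpha: np.ndarray, values: np.ndarray, nodes_rad: np.ndarray) -> np.ndarray:
    """Linear interpolation at the nodes; NaN outside the sampled span or
    where flanking samples are absent."""
    m = np.isfinite(values)
    out = np.full(nodes_rad.shape, np.nan)
    if m.sum() == 0:
        return out
    a, v = alpha[m], values[m]
    inside = (nodes_rad >= a[0] - 1e-12) & (nodes_rad <= a[-1] + 1e-12)
    out[inside] = np.interp(nodes_rad[inside], a, v)
    return out


def node_residuals(record: CochleaRecord, pred: PredictedCochlea) -> NodeResiduals:
    """Evaluate measured − predicted at every 90° node of the specimen.

    Nodes run 0°, 90°, … up to the specimen's angular length.  Absent
    measurements propagate as NaN residuals.  Raises
    :class:`ValidationError` when no node has any measurement.
    """
    n_nodes = int(math.floor(record.angular_length / NODE_STEP_DEG + 1e-9)) + 1
    nodes_deg = np.arange(n_nodes) * NODE_STEP_DEG
    nodes_rad = np.radians(nodes_deg)

    measured_r = _interp_nodes(record.radius.alpha, record.radius.r, nodes_rad)
    measured_h = _interp_nodes(record.height.alpha, record.height.h, nodes_rad)
    if not (np.isfinite(measured_r).any() or np.isfinite(measured_h).any()):
        raise ValidationError(f"record {record.id!r}: no measurable 90-degree node overlaps the profiles")

    r_res = measured_r - pred.radius_coeffs(nodes_rad)
    h_res = measured_h - pred.height_coeffs(nodes_rad)
    ang_res = record.angular_length / 360.0 - pred.angular_length_turns
    if record.metric_length_measured is not None:
        metric_res = record.metric_length_measured - metric_length(pred)
    else:
        metric_res = math.nan
    return NodeResiduals(
        specimen_id=record.id,
        node_angles_deg=nodes_deg,
        radius_residuals=r_res,
        height_residuals=h_res,
        angular_length_residual=ang_res,
        metric_length_residual=metric_res,
    )


def loocv(population: PopulationTable, radius_model: str = "polynomial") -> list[NodeResiduals]:
    """Leave-one-out cross-validation of the full prediction pipeline.

    For every specimen, the prediction model is retrained on all other
    records and used to predict the held-out cochlea from its four base
    parameters alone; residuals are evaluated at the 90° nodes.
    """
    n = len(population)
    if n < 6:
        raise UnderdeterminedError(f"LOOCV needs at least 6 records, got {n}")
    out = []
    for i, rec in enumerate(population):
        rest = PopulationTable([r for j, r in enumerate(population) if j != i])
        try:
            model = train(rest, radius_model=radius_model)
        except CochleaError as exc:
            raise CochleaError(f"LOOCV fold leaving out {rec.id!r} failed: {exc}") from None
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # implausible folds still yield residuals
            pred = predict(model, rec.base)
        out.append(node_residuals(rec, pred))
    return out


def loocv_summary(residuals: list[NodeResiduals]) -> dict:
    """Mean squared LOOCV residuals per validated quantity.

    These are the maximum-likelihood estimates of the mean squared
    prediction errors for radius (mm²), height (mm²), angular length
    (turns²) and metric length (mm², over specimens with a measured length).
    """
    r = np.concatenate([x.radius_residuals for x in residuals])
    h = np.concatenate([x.height_residuals for x in residuals])
    ang = np.array([x.angular_length_residual for x in residuals])
    met = np.array([x.metric_length_residual for x in residuals])
    met = met[np.isfinite(met)]

    def msq(v):
        v = v[np.isfinite(v)]
        return float(v @ v / v.size) if v.size else math.nan

    return {
        "mse_radius_mm2": msq(r),
        "mse_height_mm2": msq(h),
        "mse_angular_length_turns2": msq(ang),
        "mse_metric_length_mm2": msq(met),
        "mean_ssr_radius_mm2": float(np.mean([x.ssr("radius") for x in residuals])),
        "n_specimens": len(residuals),
    }


@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of two models' per-specimen summed squared residuals.

    Differences are second − first (B − A), so comparing
    ``compare_models(polynomial, logarithmic)`` reports positive numbers
    when the logarithmic model fits worse.  ``ssr_ratio`` is
    mean(SSR_B) / mean(SSR_A).
    """

    specimen_ids: list[str]
    ssr_a: np.ndarray
    ssr_b: np.ndarray
    mean_difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    ssr_ratio: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": len(self.specimen_ids),
                "mean_difference_mm2": self.mean_difference,
                "ci95_mm2": [self.ci_low, self.ci_high],
                "t_statistic": self.t_statistic,
                "t_pvalue": self.t_pvalue,
                "wilcoxon_statistic": self.wilcoxon_statistic,
                "wilcoxon_pvalue": self.wilcoxon_pvalue,
                "ssr_ratio": self.ssr_ratio,
                "mean_ssr_a_mm2": float(np.mean(self.ssr_a)),
                "mean_ssr_b_mm2": float(np.mean(self.ssr_b)),
            },
            indent=2,
        )


def compare_models(
    residuals_a: list[NodeResiduals],
    residuals_b: list[NodeResiduals],
    quantity: str = "radius",
) -> ComparisonReport:
    """Compare two residual sets over the same specimens.

    Per-specimen SSRs are summed over available nodes only; the paired
    differences d = SSR_B − SSR_A are tested two-sided with a paired t-test
    and a Wilcoxon signed-rank test, and a t-based 95 % CI of the mean
    difference is reported together with the ratio of mean SSRs (B / A).
    """
    ids_a = [x.specimen_id for x in residuals_a]
    ids_b = [x.specimen_id for x in residuals_b]
    if set(ids_a) != set(ids_b) or len(ids_a) != len(set(ids_a)):
        diff = sorted(set(ids_a) ^ set(ids_b))
        raise ValidationError(f"specimen id mismatch between residual sets: {diff}")
    by_id_b = {x.specimen_id: x for x in residuals_b}
    ssr_a = np.array([x.ssr(quantity) for x in residuals_a])
    ssr_b = np.array([by_id_b[i].ssr(quantity) for i in ids_a])

    d = ssr_b - ssr_a
    n = d.size
    mean_d = float(np.mean(d))
    if np.allclose(d, d[0]):
        # degenerate paired sample (zero variance): tests are undefined
        t_stat, t_p = math.nan, math.nan
        w_stat, w_p = math.nan, math.nan
        half = 0.0
    else:
        t_stat, t_p = stats.ttest_rel(ssr_b, ssr_a)
        se = float(np.std(d, ddof=1) / math.sqrt(n))
        half = float(stats.t.ppf(0.975, n - 1)) * se
        w_stat, w_p = stats.wilcoxon(ssr_b, ssr_a)
    mean_a = float(np.mean(ssr_a))
    ratio = float(np.mean(ssr_b) / mean_a) if mean_a > 0 else math.nan
    return ComparisonReport(
        specimen_ids=ids_a,
        ssr_a=ssr_a,
        ssr_b=ssr_b,
        mean_difference=mean_d,
        ci_low=mean_d - half,
        ci_high=mean_d + half,
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        wilcoxon_statistic=float(w_stat),
        wilcoxon_pvalue=float(w_p),
        ssr_ratio=ratio,
    )
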