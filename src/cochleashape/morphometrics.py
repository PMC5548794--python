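"""Derived shape measures and classifications.

These scalar descriptors summarise the coiling and vertical course of a
cochlea:

* **wrapping factor** — angular length / metric length (°/mm): how tightly
  the duct is coiled per millimetre of lateral wall;
* **radii ratio** — base radius / apex radius, the quantity at the heart of
  the "whispering gallery" sound-focusing hypothesis.  The base radius is
  the mean sampled r over [0°, 90°] and the apex radius the mean over the
  final 90° of the measured profile (window means are robust to
  single-sample noise; the windowing itself is a package convention);
* **B-ratio** — B_a/(B_a+B_b), how asymmetrically the modiolus cuts the
  B-axis (ratio_A = A_b/A and ratio_B = B_b/B are kept under their own
  names, since B-ratio and ratio_B are complementary);
* **vertical-profile class** — "rollercoaster" (an initial descent with a
  distinct minimum in the second half of the first turn, then re-ascent)
  versus "sloping" (steadily ascending).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CochleaRecord, HeightProfile, PopulationTable, RadiusProfile
from .errors import DomainError, ValidationError

__all__ = [
    "ShapeMetrics",
    "wrapping_factor",
    "bm_wrapping_ratio",
    "radii_ratio",
    "classify_vertical_profile",
    "quartile_groups",
    "correlation_screen",
    "shape_metrics",
    "population_metrics",
]

from .population import BASILAR_MEMBRANE_FRACTION

#: Default depth (mm) a first-turn dip must reach to count as rollercoaster.
ROLLERCOASTER_DEPTH_MM = 0.1


@dataclass(frozen=True)
class ShapeMetrics:
    """Derived descriptors of one cochlea (lengths mm, angles degrees)."""

    wrapping_factor: float  # degrees per mm
    bm_wrapping_ratio: float  # mm per degree, basilar-membrane approximated
    radii_ratio: float
    b_ratio: float  # B_a / (B_a + B_b)
    ratio_A: float  # A_b / A
    ratio_B: float  # B_b / B
    base_area: float  # mm^2, ellipse from the two base axes
    profile_class: str  # "rollercoaster" | "sloping"


def wrapping_factor(angular_length: float, metric_length: float) -> float:
    """Cochlear wrapping: angular length (°) per mm of lateral wall."""
    if not (angular_length > 0 and metric_length > 0):
        raise DomainError("wrapping factor needs positive angular and metric lengths")
    return angular_length / metric_length


def bm_wrapping_ratio(angular_length: float, metric_length: float) -> float:
    """Basilar-membrane wrapping ratio (mm/°): 0.87·metric / angular."""
    if not (angular_length > 0 and metric_length > 0):
        raise DomainError("wrapping ratio needs positive angular and metric lengths")
    return BASILAR_MEMBRANE_FRACTION * metric_length / angular_length


def radii_ratio(profile: RadiusProfile, angular_length: float) -> float:
    """Base radius over apex radius.

    Base radius = mean of present samples with α in [0°, 90°]; apex radius
    = mean of present samples within the final 90° of the measured profile.
    """
    alpha, r = profile.present()
    if alpha.size == 0:
        raise ValidationError("radii ratio: empty radius profile")
    a_deg = np.degrees(alpha)
    base = r[a_deg <= 90.0 + 1e-9]
    apex_start = a_deg[-1] - 90.0
    apex = r[a_deg >= apex_start - 1e-9]
    if base.size == 0 or apex.size == 0:
        raise ValidationError("radii ratio: profile does not cover the base and apex windows")
    apex_mean = float(np.mean(apex))
    if apex_mean <= 0:
        raise DomainError("radii ratio: apex radius must be positive")
    return float(np.mean(base)) / apex_mean


def classify_vertical_profile(
    profile: HeightProfile, depth_threshold: float = ROLLERCOASTER_DEPTH_MM
) -> str:
    """Classify the vertical trajectory as "rollercoaster" or "sloping".

    Rollercoaster: the minimum height within (180°, 360°] lies more than
    ``depth_threshold`` below the starting height *and* a later sample rises
    more than ``depth_threshold`` above that minimum.  Ties and sub-threshold
    dips are sloping.  Invariant under adding a constant to all heights.
    """
    alpha, h = profile.present()
    if alpha.size == 0 or np.degrees(alpha[-1]) < 360.0 - 1e-9:
        raise ValidationError("vertical-profile classification needs a profile spanning the first turn")
    a_deg = np.degrees(alpha)
    h0 = h[np.argmin(a_deg)] if a_deg[0] > 0 else h[0]
    window = (a_deg > 180.0) & (a_deg <= 360.0 + 1e-9)
    if not window.any():
        return "sloping"
    i_min = np.flatnonzero(window)[np.argmin(h[window])]
    h_min = h[i_min]
    dips = (h0 - h_min) > depth_threshold
    recovers = bool(np.any(h[i_min + 1 :] > h_min + depth_threshold))
    return "rollercoaster" if (dips and recovers) else "sloping"


_METRIC_FIELDS = (
    "wrapping_factor",
    "bm_wrapping_ratio",
    "radii_ratio",
    "b_ratio",
    "ratio_A",
    "ratio_B",
    "base_area",
    "angular_length",
    "metric_length",
    "A",
    "B",
)


def shape_metrics(
    record: CochleaRecord,
    metric_length_mm: float | None = None,
    depth_threshold: float = ROLLERCOASTER_DEPTH_MM,
) -> ShapeMetrics:
    """All derived descriptors for one record.

    ``metric_length_mm`` defaults to the record's independently measured
    length; wrapping measures are NaN when no metric length is available.
    """
    b = record.base
    L = metric_length_mm if metric_length_mm is not None else record.metric_length_measured
    if L is not None and L > 0:
        wf = wrapping_factor(record.angular_length, L)
        bmw = bm_wrapping_ratio(record.angular_length, L)
    else:
        wf = bmw = math.nan
    try:
        rr = radii_ratio(record.radius, record.angular_length)
    except (ValidationError, DomainError):
        rr = math.nan
    try:
        cls = classify_vertical_profile(record.height, depth_threshold)
    except ValidationError:
        cls = "sloping"
    return ShapeMetrics(
        wrapping_factor=wf,
        bm_wrapping_ratio=bmw,
        radii_ratio=rr,
        b_ratio=b.B_a / b.B,
        ratio_A=b.A_b / b.A,
        ratio_B=b.B_b / b.B,
        base_area=math.pi * (b.A / 2.0) * (b.B / 2.0),
        profile_class=cls,
    )


def population_metrics(population: PopulationTable, depth_threshold: float = ROLLERCOASTER_DEPTH_MM):
    """Per-record metric table as a dict of column → numpy array (ids in
    ``"id"``, profile class in ``"profile_class"``)."""
    cols: dict[str, list] = {k: [] for k in ("id", "profile_class") + _METRIC_FIELDS}
    for rec in population:
        m = shape_metrics(rec, depth_threshold=depth_threshold)
        cols["id"].append(rec.id)
        cols["profile_class"].append(m.profile_class)
        cols["wrapping_factor"].append(m.wrapping_factor)
        cols["bm_wrapping_ratio"].append(m.bm_wrapping_ratio)
        cols["radii_ratio"].append(m.radii_ratio)
        cols["b_ratio"].append(m.b_ratio)
        cols["ratio_A"].append(m.ratio_A)
        cols["ratio_B"].append(m.ratio_B)
        cols["base_area"].append(m.base_area)
        cols["angular_length"].append(rec.angular_length)
        cols["metric_length"].append(
            math.nan if rec.metric_length_measured is None else rec.metric_length_measured
        )
        cols["A"].append(rec.base.A)
        cols["B"].append(rec.base.B)
    return {k: (np.array(v) if k not in ("id", "profile_class") else v) for k, v in cols.items()}


def quartile_groups(population: PopulationTable, metric: str = "b_ratio") -> list[list[str]]:
    """Split records into quartile groups of a metric (sizes differ ≤ 1).

    Records are sorted by (metric value, id) — the id is the deterministic
    tie-break — and split at the empirical 25/50/75 percentiles (equal-count
    split).  Records with an undefined metric are excluded with a warning.
    """
    if len(population) < 4:
        raise ValidationError("quartile grouping needs at least 4 records")
    table = population_metrics(population)
    if metric not in table:
        raise ValidationError(f"unknown metric {metric!r}")
    pairs = []
    for rid, v in zip(table["id"], table[metric]):
        if np.isfinite(v):
            pairs.append((float(v), rid))
        else:
            import warnings

            warnings.warn(f"record {rid!r} excluded from quartile grouping: {metric} undefined")
    pairs.sort()
    ids_sorted = [rid for _, rid in pairs]
    return [list(chunk) for chunk in np.array_split(np.array(ids_sorted, dtype=object), 4)]


def correlation_screen(population: PopulationTable, metrics: list[str] | None = None):
    """Pairwise-complete Pearson correlation screen over derived metrics.

    Returns ``(names, r_matrix, p_matrix)``; cells with fewer than 3
    complete pairs are NaN (undefined).
    """
    table = population_metrics(population)
    if metrics is None:
        metrics = [k for k in _METRIC_FIELDS]
    for m in metrics:
        if m not in table:
            raise ValidationError(f"unknown metric {m!r}")
    k = len(metrics)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = table[metrics[i]], table[metrics[j]]
            m = np.isfinite(x) & np.isfinite(y)
            if m.sum() < 3:
                continue
            if i == j:
                r_mat[i, j], p_mat[i, j] = 1.0, 0.0
                continue
            if np.std(x[m]) == 0 or np.std(y[m]) == 0:
                continue
            r, p = stats.pearsonr(x[m], y[m])
            r_mat[i, j] = r_mat[j, i] = float(r)
            p_mat[i, j] = p_mat[j, i] = float(p)
    return metrics, r_mat, p_mat
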