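"""Per-specimen data model and table I/O.

The cochlea is described in a cylindrical frame around the modiolar axis:
``r(α)`` is the distance of the lateral wall from the modiolus and ``h(α)``
the axial height, both as functions of the angular position ``α`` measured
from the basal starting point (α = 0 at the first measured point, near the
round window).  The four base parameters A_a, A_b, B_a, B_b are the segments
into which the modiolus cuts the two principal diameters (A and B axes) of
the cochlear base; they are the clinically measurable predictors of the
population model.

Conventions
-----------
* Internal angle unit is **radians**; table I/O uses degrees.
* Heights are anchored at the base: h(0) = 0, positive toward the apex.
* The canonical chirality is **left-handed**; right cochleae are mirrored
  (y → −y in the Cartesian frame), which leaves r(α), h(α) and all base
  parameters unchanged.
* Tables are UTF-8 CSV/TSV with a mandatory header row, '.' decimal
  separator and empty cells for absent values.  Leading ``#`` lines carry
  unit/chirality metadata and are ignored on read.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "BaseParameters",
    "RadiusProfile",
    "HeightProfile",
    "CochleaRecord",
    "PopulationTable",
    "convert_angle",
    "canonicalize_chirality",
    "read_population",
    "write_population",
]

#: Fixed predictor order used by every regression in the package.
PREDICTOR_NAMES = ("1", "A_a", "B_a", "A_b", "B_b")

_ANGLE_UNITS = {"degrees": 360.0, "radians": 2.0 * math.pi, "turns": 1.0}


def convert_angle(value, from_unit: str, to_unit: str):
    """Convert angles between degrees, radians and turns.

    Pure rescaling; round trips are identity to machine precision.
    """
    try:
        f = _ANGLE_UNITS[from_unit]
        t = _ANGLE_UNITS[to_unit]
    except KeyError as exc:
        raise ValidationError(f"unknown angle unit: {exc.args[0]!r}") from None
    if from_unit == to_unit:
        return value
    return np.asarray(value) * (t / f) if np.ndim(value) else value * (t / f)


@dataclass(frozen=True)
class BaseParameters:
    """The four base segments (mm): modiolar cuts of the A and B axes."""

    A_a: float
    A_b: float
    B_a: float
    B_b: float

    def __post_init__(self):
        for name in ("A_a", "A_b", "B_a", "B_b"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"base parameter {name} must be strictly positive, got {v!r}")

    @property
    def A(self) -> float:
        """Full A-axis length (mm)."""
        return self.A_a + self.A_b

    @property
    def B(self) -> float:
        """Full B-axis length (mm)."""
        return self.B_a + self.B_b

    def predictor_vector(self) -> np.ndarray:
        """Design row (1, A_a, B_a, A_b, B_b) in the package-wide order."""
        return np.array([1.0, self.A_a, self.B_a, self.A_b, self.B_b])


def _check_profile(alpha: np.ndarray, values: np.ndarray, what: str) -> None:
    if alpha.ndim != 1 or values.ndim != 1 or alpha.shape != values.shape:
        raise ValidationError(f"{what}: alpha and values must be equal-length 1-D arrays")
    if alpha.size and alpha[0] < 0:
        raise ValidationError(f"{what}: angles must be non-negative")
    if alpha.size > 1 and not np.all(np.diff(alpha) > 0):
        raise ValidationError(f"{what}: angles must be strictly increasing")


@dataclass(frozen=True)
class RadiusProfile:
    """Sampled modiolar distance of the lateral wall, r(α) in mm.

    ``alpha`` is in radians, strictly increasing; absent measurements are
    NaN in ``r`` (a cochlea may not reach every tabulated angle).
    """

    alpha: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        _check_profile(self.alpha, self.r, "RadiusProfile")
        finite = self.r[np.isfinite(self.r)]
        if finite.size and np.any(finite <= 0):
            raise ValidationError("RadiusProfile: all present radii must be > 0")

    def present(self) -> tuple[np.ndarray, np.ndarray]:
        """(alpha, r) restricted to non-absent samples."""
        m = np.isfinite(self.r)
        return self.alpha[m], self.r[m]

    def __len__(self) -> int:
        return int(self.alpha.size)


@dataclass(frozen=True)
class HeightProfile:
    """Sampled axial height h(α) in mm, base-anchored (h(0) = 0, apex positive)."""

    alpha: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))
        _check_profile(self.alpha, self.h, "HeightProfile")

    def present(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.isfinite(self.h)
        return self.alpha[m], self.h[m]

    def __len__(self) -> int:
        return int(self.alpha.size)


@dataclass(frozen=True)
class CochleaRecord:
    """One specimen: identity, base parameters and sampled wall profiles.

    ``angular_length`` is the total cochlear extent in degrees and must
    exceed one full turn; the maximum sampled angle may not exceed it.
    ``metric_length_measured`` is an optional, independently measured
    lateral-wall length in mm.
    """

    id: str
    side: str
    base: BaseParameters
    radius: RadiusProfile
    height: HeightProfile
    angular_length: float  # degrees
    metric_length_measured: float | None = None
    canonical: bool = False

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"record {self.id!r}: side must be 'left' or 'right', got {self.side!r}")
        if not self.angular_length > 360.0:
            raise ValidationError(
                f"record {self.id!r}: angular length must exceed 360 deg, got {self.angular_length}"
            )
        lim = math.radians(self.angular_length) * (1 + 1e-12)
        for prof, name in ((self.radius, "radius"), (self.height, "height")):
            if len(prof) and prof.alpha[-1] > lim:
                raise ValidationError(
                    f"record {self.id!r}: {name} sample at {math.degrees(prof.alpha[-1]):.1f} deg "
                    f"exceeds angular length {self.angular_length:.1f} deg"
                )
        if self.metric_length_measured is not None and not self.metric_length_measured > 0:
            raise ValidationError(f"record {self.id!r}: measured metric length must be > 0")


def canonicalize_chirality(record: CochleaRecord) -> CochleaRecord:
    """Mirror a record into the left-handed canonical frame.

    The scalar profiles r(α) and h(α) and the base parameters are invariant
    under the mirror (y → −y); only the side/canonical annotation changes.
    Left records are returned unchanged apart from the annotation; applying
    the operation twice is the identity on the canonical frame.
    """
    if record.side not in ("left", "right"):
        raise ValidationError("record has no side set")
    return replace(record, canonical=True)


@dataclass
class PopulationTable:
    """A collection of cochlea records with unique ids."""

    records: list[CochleaRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate specimen ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


_META_COLUMNS = ["id", "side", "A_a", "A_b", "B_a", "B_b", "angular_length_deg"]
_SAMPLE_COLUMNS = ["alpha_deg", "r_mm", "h_mm"]
_OPTIONAL_COLUMNS = ["metric_length_mm"]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and not math.isfinite(x):
        return ""
    return repr(float(x)) if isinstance(x, float) else str(x)


def write_population(
    table: PopulationTable, path, delimiter: str = ",", header_comment: str | None = None
) -> None:
    """Write a population as a long-format delimited table.

    One row per angular sample; per-specimen metadata repeats on each of its
    rows.  Empty cells encode absent values.  A ``#`` comment header records
    the unit and chirality conventions (and any extra provenance passed via
    ``header_comment``).
    """
    cols = _META_COLUMNS + _OPTIONAL_COLUMNS + _SAMPLE_COLUMNS
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("# cochleashape population table\n")
        fh.write("# units: lengths mm, angles degrees; empty cell = absent value\n")
        fh.write("# chirality: canonical frame is left-handed (right cochleae mirror y -> -y)\n")
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(cols)
        for rec in table:
            meta = [
                rec.id,
                rec.side,
                _fmt(rec.base.A_a),
                _fmt(rec.base.A_b),
                _fmt(rec.base.B_a),
                _fmt(rec.base.B_b),
                _fmt(rec.angular_length),
                _fmt(rec.metric_length_measured),
            ]
            r_map = dict(zip(rec.radius.alpha.tolist(), rec.radius.r.tolist()))
            h_map = dict(zip(rec.height.alpha.tolist(), rec.height.h.tolist()))
            for a in sorted(set(r_map) | set(h_map)):
                r = r_map.get(a, math.nan)
                h = h_map.get(a, math.nan)
                w.writerow(meta + [_fmt(math.degrees(a)), _fmt(r), _fmt(h)])


def _parse_float(cell: str, row_idx: int, col: str) -> float:
    cell = cell.strip()
    if cell == "":
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"non-numeric value {cell!r} in column {col!r} at data row {row_idx}") from None


def read_population(path, delimiter: str | None = None) -> PopulationTable:
    """Read a long-format population table written by :func:`write_population`.

    ``delimiter=None`` sniffs comma vs tab from the header row.  Rows are
    grouped by specimen id; each group must carry consistent metadata.
    Raises :class:`FormatError` for missing columns or non-numeric cells and
    :class:`ValidationError` for invariant violations, naming the offender.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        return PopulationTable([])
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.reader(io.StringIO("".join(lines)), delimiter=delimiter)
    header = [c.strip() for c in next(reader)]
    missing = [c for c in _META_COLUMNS + _SAMPLE_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in header}
    has_metric = "metric_length_mm" in idx

    groups: dict[str, dict] = {}
    order: list[str] = []
    for row_idx, row in enumerate(reader, start=1):
        if not any(cell.strip() for cell in row):
            continue
        rid = row[idx["id"]].strip()
        side = row[idx["side"]].strip()
        meta = tuple(_parse_float(row[idx[c]], row_idx, c) for c in ("A_a", "A_b", "B_a", "B_b", "angular_length_deg"))
        metric = _parse_float(row[idx["metric_length_mm"]], row_idx, "metric_length_mm") if has_metric else math.nan
        sample = tuple(_parse_float(row[idx[c]], row_idx, c) for c in _SAMPLE_COLUMNS)
        g = groups.get(rid)
        if g is None:
            groups[rid] = g = {"side": side, "meta": meta, "metric": metric, "samples": []}
            order.append(rid)
        else:
            same = g["side"] == side and all(
                (math.isnan(a) and math.isnan(b)) or a == b for a, b in zip(g["meta"], meta)
            )
            if not same:
                raise ValidationError(f"duplicate id {rid!r} with inconsistent metadata at data row {row_idx}")
        g["samples"].append(sample)

    records = []
    for rid in order:
        g = groups[rid]
        A_a, A_b, B_a, B_b, ang = g["meta"]
        try:
            base = BaseParameters(A_a=A_a, A_b=A_b, B_a=B_a, B_b=B_b)
            samples = sorted(g["samples"])
            alpha = np.radians([s[0] for s in samples])
            records.append(
                CochleaRecord(
                    id=rid,
                    side=g["side"],
                    base=base,
                    radius=RadiusProfile(alpha=alpha, r=np.array([s[1] for s in samples])),
                    height=HeightProfile(alpha=alpha, h=np.array([s[2] for s in samples])),
                    angular_length=ang,
                    metric_length_measured=None if math.isnan(g["metric"]) else g["metric"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"record {rid!r} rejected: {exc}") from None
    return PopulationTable(records)
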