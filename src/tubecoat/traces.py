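"""Helix-parameter extraction from traced 3D filament coordinates.

This is the measurement stage of the analysis: given ordered point traces of
filaments decorating a membrane tube, estimate the tube axis and radius
(least-squares cylinder fit), then each filament's reduced pitch, helix
angle and handedness by fitting the axial coordinate against the unwrapped
azimuth.  The per-tube results assemble into the (radius, helix angle)
dataset consumed by the elastic model.

Traces must be ordered along the filament with consecutive points advancing
less than 180 degrees in azimuth, so the azimuthal unwrap is unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .elastic import AngleRadiusDataset
from .errors import FittingError, InsufficientExtentError, ValidationError
from .helix import HelixParams

logger = logging.getLogger(__name__)

_MIN_AZIMUTH_DEG = 90.0  # default minimum azimuthal extent for a pitch fit
_RING_TOL = 1e-9  # |h|/r below this is reported as a ring


@dataclass
class FilamentTrace:
    """Ordered 3D positions (nm) of one traced filament."""

    points: np.ndarray
    tube_id: str = "tube"
    filament_id: str = "filament"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("trace points must be an (n, 3) array")
        if not np.isfinite(self.points).all():
            raise ValidationError("trace contains non-finite coordinates")
        if len(self.points) >= 2:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if (steps == 0).any():
                raise ValidationError("consecutive trace points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TubeModel:
    """Cylinder abstraction of the membrane tube: axis + radius (nm)."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius_r: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            raise ValidationError("axis_direction must be a unit vector")
        if self.radius_r <= 0:
            raise ValidationError("tube radius must be positive")

    def cylindrical(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rho, phi, z) of points about the tube axis.

        phi is measured in the plane normal to the axis, right-handed about
        ``axis_direction``; z is the coordinate along the axis.
        """
        d = self.axis_direction
        # deterministic in-plane basis: least-aligned coordinate axis
        seed = np.zeros(3)
        seed[np.argmin(np.abs(d))] = 1.0
        e1 = np.cross(d, seed)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        rel = np.asarray(points, dtype=float) - self.axis_point
        z = rel @ d
        x = rel @ e1
        y = rel @ e2
        return np.hypot(x, y), np.arctan2(y, x), z


@dataclass
class HelixFit:
    """Result of fitting a constant helix to one trace."""

    params: HelixParams
    helix_angle_deg: float
    handedness: str  # "right" | "left" | "ring"
    filament_radius_nm: float  # mean radial distance of the trace's own points
    tube_radius_nm: float
    rms_axial_residual: float


@dataclass
class TraceReport:
    """Bookkeeping for dataset assembly: which filaments were used/skipped."""

    n_traces: int = 0
    n_used: int = 0
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # (tube, filament, reason)


def _direction_sign_convention(d: np.ndarray) -> np.ndarray:
    """Flip the axis direction so its largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(d)))
    return -d if d[i] < 0 else d


def _refine_cylinder(points: np.ndarray, centroid: np.ndarray, d0: np.ndarray):
    """Local least-squares cylinder refinement around one axis initialization.

    Parameters are two direction offsets about ``d0`` (bounded, so each
    candidate stays in its own basin) and two in-plane offsets of the axis
    point; the radius is profiled out analytically.  Returns
    (axis point, direction, radius, rms residual) or None on failure.
    """
    seed = np.zeros(3)
    seed[np.argmin(np.abs(d0))] = 1.0
    e1 = np.cross(d0, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d0, e1)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b, u, v = x
        d = d0 + a * e1 + b * e2
        d /= np.linalg.norm(d)
        c = centroid + u * e1 + v * e2
        return c, d

    def radial_dist(x: np.ndarray) -> np.ndarray:
        c, d = unpack(x)
        rel = points - c
        perp = rel - np.outer(rel @ d, d)
        return np.linalg.norm(perp, axis=1)

    def resid(x: np.ndarray) -> np.ndarray:
        rho = radial_dist(x)
        return rho - rho.mean()

    span = float(np.ptp(points, axis=0).max())
    bounds = ([-0.6, -0.6, -2 * span, -2 * span], [0.6, 0.6, 2 * span, 2 * span])
    sol = least_squares(resid, np.zeros(4), bounds=bounds, method="trf")
    if not sol.success:
        return None
    c, d = unpack(sol.x)
    rho = radial_dist(sol.x)
    radius = float(rho.mean())
    if radius <= 0:
        return None
    rms = float(np.sqrt(np.mean((rho - radius) ** 2)))
    return c, d, radius, rms


def fit_tube_axis(traces: Sequence[FilamentTrace] | FilamentTrace) -> TubeModel:
    """Least-squares cylinder fit to all points of one tube's traces.

    The axis direction is initialized from each principal component of the
    pooled points in turn (the correct one depends on the helix angle: a
    near-axial filament has its axis along the largest component, a ring
    along the smallest) and (axis point, direction, radius) are refined to
    minimize squared radial residuals.  Among candidates whose residuals are
    statistically equivalent (within 10% of the best), the smallest radius
    wins: nearly planar or gently curved traces also admit enormous grazing
    cylinders that fit within noise, and those are never the membrane tube.
    """
    if isinstance(traces, FilamentTrace):
        traces = [traces]
    points = np.concatenate([t.points for t in traces], axis=0)
    if len(points) < 10:
        raise FittingError(f"cylinder fit needs >= 10 points, got {len(points)}")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise FittingError("points are collinear; cannot fit a cylinder")

    candidates = []
    for d0 in vt:
        fit = _refine_cylinder(points, centroid, d0)
        if fit is not None:
            candidates.append(fit)
    if not candidates:
        raise FittingError("cylinder fit did not converge from any initialization")
    best_rms = min(fit[3] for fit in candidates)
    tol = 1.10 * best_rms + 1e-12
    c, d, radius, rms = min(
        (fit for fit in candidates if fit[3] <= tol), key=lambda fit: fit[2]
    )
    d = _direction_sign_convention(d)
    return TubeModel(axis_point=c, axis_direction=d, radius_r=radius, rms_residual=rms)


def helix_from_trace(
    trace: FilamentTrace,
    tube: TubeModel,
    min_azimuth_deg: float = _MIN_AZIMUTH_DEG,
    radius_source: str = "tube",
) -> HelixFit:
    """Helix parameters of one filament trace about a fitted tube axis.

    Points are expressed in cylindrical coordinates about the tube axis, the
    azimuth is unwrapped assuming consecutive points advance < 180 degrees,
    and ``z = h*phi + c`` is fitted by least squares.  The helix angle is
    ``theta = atan(|h| / r)``, with ``r`` the tube radius by default or the
    filament's own mean radial distance (``radius_source="filament"``),
    since tube diameters can vary along their length.  Handedness is the
    sign of ``h`` (positive = right-handed), independent of the sign chosen
    for the axis direction and of the point ordering.
    """
    if len(trace) < 6:
        raise InsufficientExtentError(
            f"helix fit needs >= 6 points, got {len(trace)} "
            f"({trace.tube_id}/{trace.filament_id})"
        )
    if radius_source not in ("tube", "filament"):
        raise ValidationError("radius_source must be 'tube' or 'filament'")
    rho, phi, z = tube.cylindrical(trace.points)
    if np.any(rho < 1e-6):
        raise ValidationError("trace point lies on the tube axis; azimuth undefined")
    phi = np.unwrap(phi)
    extent = float(phi.max() - phi.min())
    if math.degrees(extent) < min_azimuth_deg:
        raise InsufficientExtentError(
            f"azimuthal extent {math.degrees(extent):.1f} deg < "
            f"{min_azimuth_deg} deg; pitch is not identifiable "
            f"({trace.tube_id}/{trace.filament_id})"
        )
    h, c = np.polyfit(phi, z, 1)
    filament_radius = float(rho.mean())
    r = tube.radius_r if radius_source == "tube" else filament_radius
    theta = math.degrees(math.atan2(abs(h), r))
    if abs(h) < _RING_TOL * r:
        handedness = "ring"
        h = 0.0
    else:
        handedness = "right" if h > 0 else "left"
    rms = float(np.sqrt(np.mean((z - (h * phi + c)) ** 2)))
    return HelixFit(
        params=HelixParams(radius_r=r, reduced_pitch_h=float(h)),
        helix_angle_deg=theta,
        handedness=handedness,
        filament_radius_nm=filament_radius,
        tube_radius_nm=tube.radius_r,
        rms_axial_residual=rms,
    )


def dataset_from_traces(
    traces: Iterable[FilamentTrace],
    tubes: dict[str, TubeModel] | None = None,
    min_azimuth_deg: float = _MIN_AZIMUTH_DEG,
    radius_source: str = "tube",
) -> tuple[AngleRadiusDataset, TraceReport]:
    """Assemble an angle-radius dataset from traces grouped by tube.

    Each tube's axis is fitted from all of its traces unless a prefitted
    ``TubeModel`` is supplied.  Filaments whose helix fit fails are skipped,
    logged, and counted in the returned report.
    """
    by_tube: dict[str, list[FilamentTrace]] = {}
    for t in traces:
        by_tube.setdefault(t.tube_id, []).append(t)
    if not by_tube:
        raise ValidationError("no traces supplied")

    report = TraceReport()
    records: list[tuple[str, float, float]] = []
    for tube_id, tube_traces in by_tube.items():
        report.n_traces += len(tube_traces)
        try:
            tube = tubes[tube_id] if tubes is not None else fit_tube_axis(tube_traces)
        except (FittingError, KeyError) as exc:
            for tr in tube_traces:
                report.skipped.append((tube_id, tr.filament_id, f"tube fit failed: {exc}"))
                logger.warning("skipping %s/%s: tube fit failed (%s)", tube_id, tr.filament_id, exc)
            continue
        for tr in tube_traces:
            try:
                fit = helix_from_trace(
                    tr, tube, min_azimuth_deg=min_azimuth_deg, radius_source=radius_source
                )
            except (FittingError, ValidationError) as exc:
                report.skipped.append((tube_id, tr.filament_id, str(exc)))
                logger.warning("skipping %s/%s: %s", tube_id, tr.filament_id, exc)
                continue
            records.append((tube_id, fit.params.radius_r, fit.helix_angle_deg))
            report.n_used += 1
    if not records:
        raise FittingError("no filament trace could be fitted")
    return AngleRadiusDataset.from_records(records), report


# ---------------------------------------------------------------------------
# file I/O


def read_traces_csv(path: str | Path) -> list[FilamentTrace]:
    """Read traces from a CSV with columns tube_id, filament_id, x_nm, y_nm,
    z_nm, point_order (one row per traced point)."""
    df = pd.read_csv(path)
    required = ["tube_id", "filament_id", "x_nm", "y_nm", "z_nm", "point_order"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"trace CSV missing columns: {missing}")
    traces = []
    for (tube_id, filament_id), grp in df.groupby(["tube_id", "filament_id"], sort=True):
        grp = grp.sort_values("point_order")
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        traces.append(FilamentTrace(points=pts, tube_id=str(tube_id), filament_id=str(filament_id)))
    return traces


def write_traces_csv(traces: Sequence[FilamentTrace], path: str | Path) -> None:
    rows = []
    for t in traces:
        for i, p in enumerate(t.points):
            rows.append((t.tube_id, t.filament_id, p[0], p[1], p[2], i))
    pd.DataFrame(
        rows, columns=["tube_id", "filament_id", "x_nm", "y_nm", "z_nm", "point_order"]
    ).to_csv(path, index=False)


def read_xyz(path: str | Path, tube_id: str = "tube", filament_id: str | None = None) -> FilamentTrace:
    """Read one filament from a whitespace-delimited XYZ file (x y z per line,
    nm; '#' comments allowed)."""
    pts = np.loadtxt(path, comments="#", ndmin=2)
    if pts.shape[1] < 3:
        raise ValidationError(f"{path}: expected at least 3 columns (x y z)")
    name = filament_id if filament_id is not None else Path(path).stem
    return FilamentTrace(points=pts[:, :3], tube_id=tube_id, filament_id=name)
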