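"""Differential geometry of constant helices on a cylinder.

A filament wrapped on a membrane tube of radius ``r`` at constant helix
angle follows the curve ``(r cos(phi), r sin(phi), h*phi)`` where ``2*pi*h``
is the pitch.  For that curve the Frenet curvature and torsion are

    kappa = r / (r^2 + h^2),    tau = h / (r^2 + h^2),

and the helix angle -- the deviation of the filament from a simple ring
around the tube -- is ``theta = atan(h / r)``.  The EHD4 dimer sits rotated
by a fixed offset (about 30 degrees) relative to the filament direction, so
its orientation with respect to the tube axis is ``eta = theta + offset``.

Angles are degrees at every public interface (radians are used internally);
``h`` is signed: positive means right-handed, zero a closed ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

#: Rotation of the dimer long axis relative to the filament direction (deg).
DEFAULT_DIMER_OFFSET = 30.0

#: Dimer orientation at which the dimer's footprint curvature is aligned
#: with the tube's circumferential curvature (deg).
ALIGNED_ETA = 90.0


@dataclass(frozen=True)
class HelixParams:
    """Geometric state of a constant helix on a tube.

    Parameters
    ----------
    radius_r:
        Distance of the filament centerline from the tube axis, nm. > 0.
    reduced_pitch_h:
        Pitch divided by 2*pi, nm.  Signed: positive = right-handed,
        negative = left-handed, zero = closed ring.
    """

    radius_r: float
    reduced_pitch_h: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.radius_r) or self.radius_r <= 0:
            raise ValidationError(f"radius_r must be positive, got {self.radius_r}")
        if not math.isfinite(self.reduced_pitch_h):
            raise ValidationError("reduced_pitch_h must be finite")

    @property
    def pitch(self) -> float:
        """Axial advance per full turn, 2*pi*h (nm, signed)."""
        return 2.0 * math.pi * self.reduced_pitch_h


@dataclass(frozen=True)
class FilamentGeometry:
    """Derived curvature/twist/orientation of a constant helix.

    ``curvature_kappa`` and ``twist_tau`` are in 1/nm; ``twist_tau`` is
    signed (positive = right-handed).  ``helix_angle_theta`` is the unsigned
    helix angle in degrees, in [0, 90); ``dimer_orientation_eta`` is
    theta + dimer offset, degrees.
    """

    curvature_kappa: float
    twist_tau: float
    helix_angle_theta: float
    dimer_orientation_eta: float

    @property
    def handedness(self) -> str:
        if self.twist_tau > 0:
            return "right"
        if self.twist_tau < 0:
            return "left"
        return "ring"


def geometry_from_helix(
    params: HelixParams, offset: float = DEFAULT_DIMER_OFFSET
) -> FilamentGeometry:
    """Curvature, twist, helix angle and dimer orientation of a helix.

    ``offset`` is the dimer orientation offset in degrees (eta = theta +
    offset).  theta is computed from |h| so it is always non-negative;
    handedness is carried by the sign of tau.
    """
    r, h = params.radius_r, params.reduced_pitch_h
    denom = r * r + h * h
    kappa = r / denom
    tau = h / denom
    theta = math.degrees(math.atan2(abs(h), r))
    return FilamentGeometry(
        curvature_kappa=kappa,
        twist_tau=tau,
        helix_angle_theta=theta,
        dimer_orientation_eta=theta + offset,
    )


def helix_from_angle_radius(
    theta: float, radius_r: float, handedness: str = "right"
) -> HelixParams:
    """Inverse of :func:`geometry_from_helix` on (theta, r).

    ``theta`` in degrees, in [0, 90); ``radius_r`` > 0.  The reduced pitch
    is ``h = r * tan(theta)``, signed by ``handedness``.
    """
    if radius_r <= 0:
        raise ValidationError(f"radius_r must be positive, got {radius_r}")
    if not 0.0 <= theta < 90.0:
        raise ValidationError(
            f"helix angle must be in [0, 90) degrees, got {theta} "
            "(90 degrees corresponds to infinite pitch)"
        )
    h = radius_r * math.tan(math.radians(theta))
    if handedness == "left":
        h = -h
    elif handedness != "right":
        raise ValidationError(f"handedness must be 'right' or 'left', got {handedness!r}")
    return HelixParams(radius_r=radius_r, reduced_pitch_h=h)


def dimer_orientation(theta: float, offset: float = DEFAULT_DIMER_OFFSET) -> float:
    """Dimer orientation relative to the tube axis: eta = theta + offset (deg)."""
    if not 0.0 <= theta < 90.0:
        raise ValidationError(f"helix angle must be in [0, 90) degrees, got {theta}")
    return theta + offset


def aligned_helix_angle(
    offset: float = DEFAULT_DIMER_OFFSET, eta_target: float = ALIGNED_ETA
) -> float:
    """Helix angle at which the dimer orientation reaches ``eta_target``.

    Solves ``dimer_orientation(theta, offset) == eta_target`` for theta by
    bracketed root finding on [0, 90).  With the default 30 degree offset the
    dimer's curvature aligns with the tube's circumferential curvature
    (eta = 90 degrees) at a helix angle of 60 degrees.
    """
    from scipy.optimize import brentq

    lo, hi = 0.0, 90.0 - 1e-9
    f_lo = dimer_orientation(lo, offset) - eta_target
    f_hi = dimer_orientation(hi, offset) - eta_target
    if f_lo == 0.0:
        return lo
    if f_lo * f_hi > 0:
        raise ValidationError(
            f"eta = {eta_target} deg is not reached for any helix angle in "
            f"[0, 90) with offset {offset} deg"
        )
    return float(brentq(lambda t: dimer_orientation(t, offset) - eta_target, lo, hi, xtol=1e-12))
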