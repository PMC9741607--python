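"""Parametric models of multi-filament helical coats on membrane tubes.

A coat is one or more congruent helical filaments of dimer subunits wrapped
on a cylinder.  A lattice is specified by the tube radius, the filament
helix angle, the arc-length spacing between dimer centers along a filament,
and the number of parallel filament starts; from these follow the helical
family parameters (pitch, rise per subunit, subunits per turn).  Subunits
are placed as position + right-handed orthonormal frame (filament tangent,
outward tube normal, binormal); dimer internal structure is not modelled.

The tube axis is the z axis through the origin; exporters accept an
optional rigid transform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import ValidationError
from .helix import DEFAULT_DIMER_OFFSET

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ" "abcdefghijklmnopqrstuvwxyz" "0123456789"
)


@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of one helical coat family.

    ``subunit_spacing`` is the arc length between adjacent dimer centers
    along a filament (nm).  ``n_filaments`` parallel starts are offset
    uniformly in azimuth, which makes the perpendicular spacing between
    neighboring filaments (the inter-filament packing direction) uniform;
    ``phase_offsets`` (radians, one per filament) overrides that default.
    ``filament_width`` (nm), if given, enables an overlap warning when the
    starts are packed closer than one filament width.
    """

    radius_r: float
    helix_angle_theta: float  # degrees, [0, 90)
    subunit_spacing: float  # nm along the filament
    n_subunits: int
    n_filaments: int = 1
    dimer_offset: float = DEFAULT_DIMER_OFFSET
    phase_offsets: tuple[float, ...] | None = None
    filament_width: float | None = None

    def __post_init__(self) -> None:
        if self.radius_r <= 0:
            raise ValidationError("radius_r must be positive")
        if not 0.0 <= self.helix_angle_theta < 90.0:
            raise ValidationError("helix_angle_theta must be in [0, 90) degrees")
        if self.subunit_spacing <= 0:
            raise ValidationError("subunit_spacing must be positive")
        if self.n_subunits < 1 or self.n_filaments < 1:
            raise ValidationError("n_subunits and n_filaments must be >= 1")
        if self.phase_offsets is not None and len(self.phase_offsets) != self.n_filaments:
            raise ValidationError("phase_offsets must have one entry per filament")


@dataclass
class CoatModel:
    """Subunit placements of a coat: positions + orientation frames.

    ``positions`` is (n, 3) in nm; ``frames`` is (n, 3, 3) with rows
    (filament tangent, outward tube normal, binormal), a right-handed
    orthonormal triad.  ``filament_index`` / ``subunit_index`` identify each
    placement.
    """

    spec: LatticeSpec
    filament_index: np.ndarray
    subunit_index: np.ndarray
    positions: np.ndarray
    frames: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def filament_positions(self, f: int) -> np.ndarray:
        return self.positions[self.filament_index == f]


@dataclass(frozen=True)
class CoatGeometry:
    """Helical family parameters derived from a lattice spec."""

    pitch: float  # nm per turn; 0 for a ring
    rise_per_subunit: float  # nm
    subunits_per_turn: float  # inf flags a ring
    is_ring: bool


def coat_pitch_and_rise(spec: LatticeSpec) -> CoatGeometry:
    """Pitch, rise per subunit and subunits per turn of the family.

    pitch = 2*pi*r*tan(theta); rise = spacing*sin(theta);
    subunits_per_turn = pitch / rise.  A ring (theta = 0) has zero pitch and
    rise and is flagged with an infinite subunits-per-turn.
    """
    theta = math.radians(spec.helix_angle_theta)
    if spec.helix_angle_theta == 0.0:
        return CoatGeometry(pitch=0.0, rise_per_subunit=0.0,
                            subunits_per_turn=math.inf, is_ring=True)
    pitch = 2.0 * math.pi * spec.radius_r * math.tan(theta)
    rise = spec.subunit_spacing * math.sin(theta)
    return CoatGeometry(pitch=pitch, rise_per_subunit=rise,
                        subunits_per_turn=pitch / rise, is_ring=False)


def subunits_per_ring(spec: LatticeSpec) -> float:
    """Subunits closing one full ring at theta = 0: circumference / spacing."""
    return 2.0 * math.pi * spec.radius_r / spec.subunit_spacing


def build_coat(spec: LatticeSpec) -> CoatModel:
    """Place subunits along n congruent helices on the tube surface.

    Along one filament the azimuth advances by ``spacing*cos(theta)/r`` and
    the axial coordinate by ``spacing*sin(theta)`` per subunit, so
    consecutive placements are exactly ``subunit_spacing`` apart in arc
    length.  Filament starts are offset by 2*pi/n in azimuth (uniform
    inter-filament spacing) unless ``phase_offsets`` overrides them.
    """
    r = spec.radius_r
    theta = math.radians(spec.helix_angle_theta)
    dphi = spec.subunit_spacing * math.cos(theta) / r  # azimuth per subunit
    dz = spec.subunit_spacing * math.sin(theta)  # rise per subunit

    if spec.phase_offsets is not None:
        offsets = np.asarray(spec.phase_offsets, dtype=float)
    else:
        offsets = 2.0 * math.pi * np.arange(spec.n_filaments) / spec.n_filaments

    if spec.filament_width is not None and spec.n_filaments > 1:
        gap = (2.0 * math.pi * r / spec.n_filaments) * math.sin(theta)
        if 0 < gap < spec.filament_width:
            warnings.warn(
                f"{spec.n_filaments} starts of width {spec.filament_width} nm "
                f"overlap: perpendicular inter-filament spacing is {gap:.2f} nm",
                stacklevel=2,
            )

    k = np.arange(spec.n_subunits)
    fil_idx, sub_idx, pos, frames = [], [], [], []
    for f, phi0 in enumerate(offsets):
        phi = phi0 + k * dphi
        z = k * dz
        cos_p, sin_p = np.cos(phi), np.sin(phi)
        xyz = np.column_stack([r * cos_p, r * sin_p, z])
        tangent = np.column_stack(
            [-sin_p * math.cos(theta), cos_p * math.cos(theta),
             np.full_like(phi, math.sin(theta))]
        )
        normal = np.column_stack([cos_p, sin_p, np.zeros_like(phi)])
        binormal = np.cross(tangent, normal)
        fil_idx.append(np.full(spec.n_subunits, f, dtype=int))
        sub_idx.append(k.copy())
        pos.append(xyz)
        frames.append(np.stack([tangent, normal, binormal], axis=1))
    return CoatModel(
        spec=spec,
        filament_index=np.concatenate(fil_idx),
        subunit_index=np.concatenate(sub_idx),
        positions=np.concatenate(pos),
        frames=np.concatenate(frames),
    )


def coat_to_traces(model: CoatModel):
    """One FilamentTrace per filament from a coat's placement positions."""
    from .traces import FilamentTrace

    traces = []
    for f in np.unique(model.filament_index):
        pts = model.filament_positions(int(f))
        if len(pts) >= 2:
            traces.append(
                FilamentTrace(points=pts, tube_id="coat", filament_id=f"filament_{int(f)}")
            )
    return traces


def _apply_transform(positions: np.ndarray, rotation, translation) -> np.ndarray:
    out = positions
    if rotation is not None:
        out = out @ np.asarray(rotation, dtype=float).T
    if translation is not None:
        out = out + np.asarray(translation, dtype=float)
    return out


def export_coat(
    model: CoatModel,
    path: str | Path,
    format: str | None = None,
    rotation=None,
    translation=None,
) -> Path:
    """Write a coat as CSV (positions + frame vectors) or PDB pseudo-atoms.

    The PDB dialect writes one CA pseudo-atom per placement in Angstrom
    (nm x 10), one chain per filament (62-chain limit), residue number and
    B-factor = subunit index.  An optional rigid transform (rotation matrix,
    translation in nm) is applied to positions before writing.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    pos = _apply_transform(model.positions, rotation, translation)

    if fmt == "csv":
        df = pd.DataFrame(
            {
                "filament_index": model.filament_index,
                "subunit_index": model.subunit_index,
                "x_nm": pos[:, 0],
                "y_nm": pos[:, 1],
                "z_nm": pos[:, 2],
            }
        )
        for name, j in (("tangent", 0), ("normal", 1), ("binormal", 2)):
            vec = model.frames[:, j, :]
            if rotation is not None:
                vec = vec @ np.asarray(rotation, dtype=float).T
            for axis, i in (("x", 0), ("y", 1), ("z", 2)):
                df[f"{name}_{axis}"] = vec[:, i]
        df.to_csv(path, index=False, float_format="%.9g")
        return path

    if fmt == "pdb":
        n_fil = int(model.filament_index.max()) + 1
        if n_fil > len(_CHAIN_IDS):
            raise ValidationError(
                f"PDB export supports at most {len(_CHAIN_IDS)} filaments (chains), got {n_fil}"
            )
        structure = gemmi.Structure()
        structure.name = "coat"
        gm = gemmi.Model("1")
        for f in range(n_fil):
            chain = gemmi.Chain(_CHAIN_IDS[f])
            sel = np.nonzero(model.filament_index == f)[0]
            for i in sel:
                res = gemmi.Residue()
                res.name = "ALA"
                res.seqid = gemmi.SeqId(int(model.subunit_index[i]) + 1, " ")
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*(pos[i] * 10.0))  # nm -> Angstrom
                atom.b_iso = float(model.subunit_index[i])
                atom.occ = 1.0
                res.add_atom(atom)
                chain.add_residue(res)
            gm.add_chain(chain)
        structure.add_model(gm)
        structure.setup_entities()
        structure.write_pdb(str(path))
        return path

    raise ValidationError(f"unknown export format {fmt!r} (use 'csv' or 'pdb')")


def read_coat_csv(path: str | Path) -> pd.DataFrame:
    """Reparse an exported coat CSV (round-trips positions)."""
    return pd.read_csv(path)
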