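"""Seeded generators for every input the analysis pipeline consumes.

These emulate the tomographic measurements the model is fitted to: membrane
tubes with radii in the experimentally observed 15-70 nm range, filament
helix angles scattered about the elastic-model curve with Gaussian noise,
noisy 3D point traces of helical filaments, and multi-filament coats.  All
generators are pure functions of (configuration, seed).

The defaults describe the study conditions: 50 tubes drawn uniformly on
15-70 nm, spontaneous curvature 1/68 1/nm, 5 degree angle noise (the
measurement error of the traced angles is not known; 5 degrees is a
realistic figure for hand-traced tomogram filaments, not a measured one),
and 0.5 nm isotropic positional noise on traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np

from .coat import LatticeSpec, build_coat
from .elastic import AngleRadiusDataset, ElasticParams, curvature_only_params, predicted_angles
from .errors import ValidationError
from .helix import HelixParams
from .traces import FilamentTrace

_THETA_CLIP = 89.9  # observed angles clipped below the 90 deg domain edge


def _default_regime() -> ElasticParams:
    return curvature_only_params(kappa0=1.0 / 68.0)


@dataclass
class SimulationConfig:
    """Conditions for simulating an angle-radius dataset.

    ``radius_range`` defaults to the 15-70 nm band where ordered oligomers
    are observed; ``kappa0_true``/``tau0_true`` are the generating
    spontaneous curvature/twist and ``regime`` the energy used to map radius
    to true helix angle.  ``angle_noise_sd`` (degrees) is added to the true
    angle and the result truncated to [0, 89.9] degrees.
    """

    seed: int = 0
    n_tubes: int = 50
    radius_range: tuple[float, float] = (15.0, 70.0)
    kappa0_true: float = 1.0 / 68.0
    tau0_true: float = 0.0
    regime: ElasticParams | None = None
    angle_noise_sd: float = 5.0
    trace_point_noise_sd: float = 0.5
    points_per_filament: int = 50
    radius_distribution: str = "uniform"  # or "log-uniform"

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not (0 < lo < hi):
            raise ValidationError("radius_range must satisfy 0 < low < high")
        if self.angle_noise_sd < 0 or self.trace_point_noise_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        if self.n_tubes < 1:
            raise ValidationError("n_tubes must be >= 1")
        if self.radius_distribution not in ("uniform", "log-uniform"):
            raise ValidationError("radius_distribution must be 'uniform' or 'log-uniform'")

    def effective_regime(self) -> ElasticParams:
        if self.regime is not None:
            return self.regime
        from dataclasses import replace

        return replace(_default_regime(), kappa0=self.kappa0_true, tau0=self.tau0_true)


def simulate_angle_radius_dataset(cfg: SimulationConfig) -> AngleRadiusDataset:
    """Draw tubes and noisy helix angles from the elastic model.

    Radii are uniform (or log-uniform) on ``cfg.radius_range``; the true
    angle at each radius is the elastic-model prediction under
    ``cfg.regime``; Gaussian noise of SD ``cfg.angle_noise_sd`` is added and
    the observation truncated to the valid angle domain.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.radius_range
    if cfg.radius_distribution == "uniform":
        radii = rng.uniform(lo, hi, size=cfg.n_tubes)
    else:
        radii = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_tubes))
    theta_true = predicted_angles(radii, cfg.effective_regime())
    theta_obs = theta_true + rng.normal(0.0, cfg.angle_noise_sd, size=cfg.n_tubes)
    theta_obs = np.clip(theta_obs, 0.0, _THETA_CLIP)
    records = [
        (f"tube_{i:03d}", float(radii[i]), float(theta_obs[i])) for i in range(cfg.n_tubes)
    ]
    return AngleRadiusDataset.from_records(records)


def simulate_helix_trace(
    params: HelixParams,
    n_points: int = 50,
    arc_extent: float | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    tube_id: str = "tube",
    filament_id: str = "filament",
    phase0: float = 0.0,
) -> FilamentTrace:
    """Uniformly arc-length-sampled points on a helix plus isotropic noise.

    ``arc_extent`` is the total arc length sampled (nm); the default covers
    1.5 turns.  The helix axis is z through the origin.
    """
    if n_points < 6:
        raise ValidationError("a trace needs at least 6 points")
    r, h = params.radius_r, params.reduced_pitch_h
    speed = math.hypot(r, h)  # arc length per radian of azimuth
    if arc_extent is None:
        arc_extent = 1.5 * 2.0 * math.pi * speed
    s = np.linspace(0.0, arc_extent, n_points)
    phi = phase0 + s / speed
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), h * phi])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return FilamentTrace(points=pts, tube_id=tube_id, filament_id=filament_id)


def simulate_coat_point_cloud(
    spec: LatticeSpec,
    noise_sd: float = 0.0,
    seed: int | None = None,
    tube_id: str = "coat",
) -> list[FilamentTrace]:
    """Jitter a built coat's placements into per-filament traces.

    One trace per filament start, all tagged with a shared tube id, with
    isotropic Gaussian noise of SD ``noise_sd`` on the positions.
    """
    model = build_coat(spec)
    rng = np.random.default_rng(seed)
    traces = []
    for f in range(spec.n_filaments):
        pts = model.filament_positions(f)
        if noise_sd > 0:
            pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
        traces.append(
            FilamentTrace(points=pts, tube_id=tube_id, filament_id=f"filament_{f}")
        )
    return traces


def simulate_tube_traces(
    cfg: SimulationConfig,
    filaments_per_tube: int = 1,
    turns: float = 1.5,
    subunit_spacing: float = 7.0,
) -> list[FilamentTrace]:
    """Full-pipeline fixture: noisy filament traces for every simulated tube.

    For each tube a radius is drawn as in
    :func:`simulate_angle_radius_dataset`, the true helix angle taken from
    the elastic model, and ``filaments_per_tube`` traces generated with
    ``cfg.trace_point_noise_sd`` positional noise, each covering ``turns``
    helical turns with ``cfg.points_per_filament`` points.  Every tube uses
    its own canonical frame (axis = z); downstream analysis fits each tube
    independently via its tube_id, so no global arrangement is implied.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.radius_range
    regime = cfg.effective_regime()
    traces: list[FilamentTrace] = []
    for i in range(cfg.n_tubes):
        if cfg.radius_distribution == "uniform":
            r = float(rng.uniform(lo, hi))
        else:
            r = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        theta = float(predicted_angles([r], regime)[0])
        h = r * math.tan(math.radians(theta))
        params = HelixParams(radius_r=r, reduced_pitch_h=h)
        arc = turns * 2.0 * math.pi * math.hypot(r, h)
        for f in range(filaments_per_tube):
            tr = simulate_helix_trace(
                params,
                n_points=cfg.points_per_filament,
                arc_extent=arc,
                noise_sd=cfg.trace_point_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                tube_id=f"tube_{i:03d}",
                filament_id=f"filament_{f}",
                phase0=2.0 * math.pi * f / filaments_per_tube,
            )
            traces.append(tr)
    return traces
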