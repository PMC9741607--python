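"""Elastic filament-on-tube model and spontaneous-curvature fitting.

The model assigns a constant helix of angle ``theta`` on a tube of radius
``r`` the elastic energy (arbitrary units)

    E = k_kappa * (kappa - kappa0)^2
      + k_tau   * (tau   - tau0  )^2
      + k_eta   * (eta   - eta0  )^2

with ``kappa = cos^2(theta)/r``, ``tau = sin(theta)cos(theta)/r`` and
``eta = theta + dimer_offset``.  ``kappa0`` and ``tau0`` are the spontaneous
curvature and twist of the filament (1/nm); ``eta0 = 90 deg`` expresses a
preference for the dimer footprint curvature to align perpendicular to the
tube axis.  The predicted helix angle ``theta(r)`` minimizes E over theta at
fixed r.  When the twist and dimer terms vanish the minimizer has the closed
form ``tan(theta) = sqrt(1/(r*kappa0) - 1)`` for ``r < 1/kappa0`` and
``theta = 0`` (a ring) for larger tubes.

Spontaneous curvature (and optionally twist) are estimated from observed
(tube radius, helix angle) pairs by least squares on the angles, with a
seeded percentile bootstrap for the kappa0 confidence range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .errors import ConfigurationError, FittingError, ValidationError
from .helix import DEFAULT_DIMER_OFFSET, FilamentGeometry

_THETA_MAX = 90.0 - 1e-9  # open upper bound of the helix-angle domain, deg
_GRID_STEP = 0.01  # coarse minimization grid resolution, deg


@dataclass(frozen=True)
class ElasticParams:
    """Stiffness weights and spontaneous values of the elastic energy.

    Weights are dimensionless and non-negative (at least one positive);
    ``kappa0``/``tau0`` are in 1/nm.  ``eta0`` is the preferred dimer
    orientation (degrees, 90 by convention) and ``dimer_offset`` the fixed
    rotation of the dimer relative to the filament (degrees).  The unit in
    which the eta deviation enters the energy is configurable because the
    relative weight of the eta term depends on it; the default is radians.
    """

    k_kappa: float = 1.0
    k_tau: float = 0.0
    k_eta: float = 0.0
    kappa0: float = 0.0
    tau0: float = 0.0
    eta0: float = 90.0
    dimer_offset: float = DEFAULT_DIMER_OFFSET
    angle_unit_in_energy: str = "radians"

    def __post_init__(self) -> None:
        for name in ("k_kappa", "k_tau", "k_eta"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.k_kappa == self.k_tau == self.k_eta == 0:
            raise ConfigurationError("at least one elastic weight must be positive")
        if self.angle_unit_in_energy not in ("radians", "degrees"):
            raise ValidationError("angle_unit_in_energy must be 'radians' or 'degrees'")
        if self.k_kappa > 0 and self.kappa0 < 0:
            raise ValidationError("kappa0 must be non-negative when the curvature term is active")

    @property
    def is_curvature_only(self) -> bool:
        return self.k_tau == 0 and self.k_eta == 0 and self.k_kappa > 0


def curvature_only_params(kappa0: float) -> ElasticParams:
    """Regime with twist elasticity and dimer orientation negligible."""
    return ElasticParams(k_kappa=1.0, k_tau=0.0, k_eta=0.0, kappa0=kappa0)


def curvature_twist_params(kappa0: float, tau0: float = 0.0) -> ElasticParams:
    """Regime typical for continuous filaments: curvature + twist terms."""
    return ElasticParams(k_kappa=1.0, k_tau=1.0, k_eta=0.0, kappa0=kappa0, tau0=tau0)


def curvature_dimer_params(kappa0: float, k_eta: float = 0.2) -> ElasticParams:
    """Regime adding a preference for the dimer curvature to align with the tube."""
    return ElasticParams(k_kappa=1.0, k_tau=0.0, k_eta=k_eta, kappa0=kappa0)


@dataclass
class AngleRadiusDataset:
    """Per-filament (tube radius, helix angle) observations.

    Backed by a DataFrame with columns ``tube_id``, ``radius_nm``,
    ``helix_angle_deg``; one row per filament.
    """

    table: pd.DataFrame

    COLUMNS = ("tube_id", "radius_nm", "helix_angle_deg")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"dataset missing columns: {missing}")
        r = self.table["radius_nm"].to_numpy(dtype=float)
        th = self.table["helix_angle_deg"].to_numpy(dtype=float)
        if not (np.isfinite(r).all() and np.isfinite(th).all()):
            raise ValidationError("non-finite radius or helix angle in dataset")
        if (r <= 0).any():
            raise ValidationError("all radii must be positive")
        if ((th < 0) | (th >= 90)).any():
            raise ValidationError("helix angles must lie in [0, 90) degrees")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, float, float]]
    ) -> "AngleRadiusDataset":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleRadiusDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.loc[:, list(self.COLUMNS)].to_csv(path, index=False)

    @property
    def radii(self) -> np.ndarray:
        return self.table["radius_nm"].to_numpy(dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return self.table["helix_angle_deg"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FitResult:
    """Outcome of fitting spontaneous parameters to an angle-radius dataset."""

    params: ElasticParams
    rss: float  # residual sum of squares, deg^2
    n_obs: int
    free: tuple[str, ...]
    residuals: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    kappa0_range: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "kappa0": self.params.kappa0,
            "tau0": self.params.tau0,
            "k_kappa": self.params.k_kappa,
            "k_tau": self.params.k_tau,
            "k_eta": self.params.k_eta,
            "free_parameters": list(self.free),
            "rss_deg2": self.rss,
            "n_obs": self.n_obs,
        }
        if self.kappa0_range is not None:
            d["kappa0_range"] = list(self.kappa0_range)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def tidy_table(self, data: AngleRadiusDataset) -> pd.DataFrame:
        """Per-record table of (r, observed, predicted, residual)."""
        return pd.DataFrame(
            {
                "tube_id": data.table["tube_id"].to_numpy(),
                "radius_nm": data.radii,
                "helix_angle_obs_deg": data.angles,
                "helix_angle_pred_deg": self.predicted,
                "residual_deg": self.residuals,
            }
        )


# ---------------------------------------------------------------------------
# energy and its minimizer


def _eta_scale(params: ElasticParams) -> float:
    return math.pi / 180.0 if params.angle_unit_in_energy == "radians" else 1.0


def elastic_energy(geom: FilamentGeometry, params: ElasticParams) -> float:
    """Elastic energy of a filament geometry (arbitrary units, >= 0)."""
    s = _eta_scale(params)
    d_eta = (geom.dimer_orientation_eta - params.eta0) * s
    return (
        params.k_kappa * (geom.curvature_kappa - params.kappa0) ** 2
        + params.k_tau * (geom.twist_tau - params.tau0) ** 2
        + params.k_eta * d_eta**2
    )


def _energy_of_theta(theta_deg, radius_r, params: ElasticParams):
    """Vectorized energy over helix angle(s) at fixed radius (right-handed branch).

    Zero-weight terms are skipped; with broadcasting over a (radii x grid)
    array this keeps the coarse-grid minimization cheap.
    """
    t = np.radians(np.asarray(theta_deg, dtype=float))
    r = np.asarray(radius_r, dtype=float)
    shape = np.broadcast_shapes(t.shape, r.shape)
    c = np.cos(t)
    terms = []
    if params.k_kappa > 0:
        d = c * c / r
        d -= params.kappa0
        np.square(d, out=d)
        if params.k_kappa != 1.0:
            d *= params.k_kappa
        terms.append(d)
    if params.k_tau > 0:
        d = np.sin(t) * c / r
        d -= params.tau0
        np.square(d, out=d)
        if params.k_tau != 1.0:
            d *= params.k_tau
        terms.append(d)
    if params.k_eta > 0:
        s = _eta_scale(params)
        d = (np.asarray(theta_deg, dtype=float) + (params.dimer_offset - params.eta0)) * s
        np.square(d, out=d)
        d *= params.k_eta
        terms.append(d)
    energy = terms[0]
    if energy.shape != shape:
        energy = np.broadcast_to(energy, shape).copy()
    for d in terms[1:]:
        energy += d
    return energy if energy.shape else float(energy)


def analytic_angle(radius_r, kappa0: float):
    """Closed-form minimum-energy helix angle for the curvature-only regime.

    For ``r < 1/kappa0`` the filament can reach its spontaneous curvature by
    tilting: ``theta = atan(sqrt(1/(r*kappa0) - 1))``.  For ``r >= 1/kappa0``
    the spontaneous curvature is unreachable, the energy is monotone in
    kappa, and the minimum sits at the ring, theta = 0.  Accepts scalars or
    arrays; returns degrees.
    """
    r = np.asarray(radius_r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("radius must be positive")
    if kappa0 <= 0:
        raise ValidationError("kappa0 must be positive")
    x = 1.0 / (r * kappa0) - 1.0
    theta = np.degrees(np.arctan(np.sqrt(np.clip(x, 0.0, None))))
    return float(theta) if np.isscalar(radius_r) else theta


def predicted_angles(radii, params: ElasticParams, grid_step: float = _GRID_STEP) -> np.ndarray:
    """Energy-minimizing helix angle for each radius (degrees), vectorized.

    Deterministic coarse grid over [0, 90) followed by a quadratic (three
    point) refinement around the grid minimum; ties break toward smaller
    theta via first-argmin.
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise ValidationError("all radii must be positive")
    if params.k_kappa == params.k_tau == params.k_eta == 0:
        raise ConfigurationError("all elastic weights are zero")

    grid = np.arange(0.0, 90.0, grid_step)
    # energies: (n_radii, n_grid)
    energies = _energy_of_theta(grid[None, :], radii[:, None], params)
    idx = np.argmin(energies, axis=1)
    theta = grid[idx]

    # parabolic refinement where the minimum is interior
    interior = (idx > 0) & (idx < len(grid) - 1)
    if interior.any():
        i = idx[interior]
        rows = np.nonzero(interior)[0]
        e0 = energies[rows, i - 1]
        e1 = energies[rows, i]
        e2 = energies[rows, i + 1]
        denom = e0 - 2.0 * e1 + e2
        shift = np.zeros_like(e1)
        ok = denom > 0
        shift[ok] = 0.5 * (e0[ok] - e2[ok]) / denom[ok]
        theta[interior] = grid[i] + np.clip(shift, -1.0, 1.0) * grid_step
    return np.clip(theta, 0.0, _THETA_MAX)


def predicted_angle(radius_r: float, params: ElasticParams) -> float:
    """Helix angle minimizing the elastic energy at fixed tube radius (deg).

    Scalar front end of :func:`predicted_angles`; the grid minimum is
    polished with bounded scalar minimization for full precision.
    """
    theta0 = float(predicted_angles([radius_r], params)[0])
    lo = max(0.0, theta0 - 2 * _GRID_STEP)
    hi = min(_THETA_MAX, theta0 + 2 * _GRID_STEP)
    res = minimize_scalar(
        lambda t: float(_energy_of_theta(np.array([t]), np.array([radius_r]), params)[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # pick the lower-energy candidate; on a tie, the smaller angle
    candidates = sorted(
        [(float(_energy_of_theta(np.array([theta0]), np.array([radius_r]), params)[0]), theta0),
         (float(res.fun), float(res.x))],
        key=lambda ef: (ef[0], ef[1]),
    )
    return candidates[0][1]


# ---------------------------------------------------------------------------
# fitting


def _predict_for_fit(radii: np.ndarray, params: ElasticParams) -> np.ndarray:
    if params.is_curvature_only:
        return analytic_angle(radii, params.kappa0)
    return predicted_angles(radii, params)


def fit_spontaneous(
    data: AngleRadiusDataset,
    regime: ElasticParams,
    free: tuple[str, ...] | None = None,
    x0: dict[str, float] | None = None,
) -> FitResult:
    """Least-squares fit of spontaneous curvature/twist to angle-radius data.

    Minimizes ``sum_i (theta_obs_i - theta_pred(r_i))^2`` in squared degrees
    over the parameters named in ``free`` (default: ``("kappa0",)``, plus
    ``"tau0"`` when the twist term is active).  Pass ``free=()`` to score a
    fully fixed regime: the result then carries the given parameters and
    their residual sum, with nothing fitted.
    """
    if free is None:
        free = ("kappa0", "tau0") if regime.k_tau > 0 else ("kappa0",)
    for name in free:
        if name not in ("kappa0", "tau0"):
            raise ValidationError(f"unknown free parameter {name!r}")

    radii = data.radii
    angles = data.angles
    n = len(data)
    if n < len(free) + 1:
        raise FittingError(
            f"need at least {len(free) + 1} records to fit {len(free)} parameter(s), got {n}"
        )

    if not free:
        pred = _predict_for_fit(radii, regime)
        resid = angles - pred
        return FitResult(
            params=regime,
            rss=float(np.sum(resid**2)),
            n_obs=n,
            free=(),
            residuals=resid,
            predicted=pred,
        )

    # moment-based starting values: the spontaneous curvature/twist of the
    # observed geometries themselves, so the initial model curve crosses the
    # data (a cold start like tau0 = 0 can park every predicted angle at the
    # 90 degree boundary, where the objective is flat)
    t_obs = np.radians(angles)
    defaults = {
        "kappa0": float(np.median(np.cos(t_obs) ** 2 / radii)),
        "tau0": float(np.median(np.sin(t_obs) * np.cos(t_obs) / radii)),
    }
    if x0:
        defaults.update(x0)
    p0 = np.array([defaults[name] for name in free])
    lower = np.array([1e-6 if name == "kappa0" else -np.inf for name in free])
    upper = np.full(len(free), np.inf)

    def residual(x: np.ndarray) -> np.ndarray:
        params = replace(regime, **dict(zip(free, x)))
        return angles - _predict_for_fit(radii, params)

    sol = least_squares(residual, p0, bounds=(lower, upper), method="trf")
    if not sol.success:
        raise FittingError(f"least-squares fit failed: {sol.message}")
    fitted = replace(regime, **dict(zip(free, sol.x)))
    pred = _predict_for_fit(radii, fitted)
    resid = angles - pred
    return FitResult(
        params=fitted,
        rss=float(np.sum(resid**2)),
        n_obs=n,
        free=tuple(free),
        residuals=resid,
        predicted=pred,
    )


def kappa0_confidence_range(
    data: AngleRadiusDataset,
    regime: ElasticParams,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Seeded nonparametric bootstrap percentile interval for kappa0.

    Records are resampled with replacement ``n_boot`` times; each resample is
    refitted and the (2.5, 97.5) percentiles (for the default 95% level) of
    the fitted kappa0 values are returned.  Degenerate resamples (e.g. a
    single repeated record) are redrawn up to ``max_retries`` times.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(data)
    table = data.table.reset_index(drop=True)
    free = ("kappa0", "tau0") if regime.k_tau > 0 else ("kappa0",)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            sample = AngleRadiusDataset(table.iloc[idx].reset_index(drop=True))
            if len(np.unique(sample.radii)) <= len(free):
                continue  # unidentifiable resample, redraw
            try:
                estimates[b] = fit_spontaneous(sample, regime, free=free).params.kappa0
                break
            except FittingError:
                continue
        else:
            raise FittingError(
                f"bootstrap replicate {b} failed after {max_retries} retries"
            )
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(low), float(high)
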