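# Methods

## The model

`tubecoat` treats a membrane-bound protein filament as an inextensible
elastic rod constrained to the surface of a cylindrical membrane tube of
radius `r` (nm). A filament wrapped at constant helix angle `θ` — measured
from the circumferential (ring) direction, so `θ = 0°` is a closed ring and
`θ → 90°` is axial — follows the constant helix
`(r cos φ, r sin φ, h φ)` with reduced pitch `h = r tan θ` (pitch `2πh`,
sign of `h` = handedness, positive right-handed). Its Frenet curvature and
torsion are

```
κ = r / (r² + h²) = cos²θ / r        τ = h / (r² + h²) = sinθ cosθ / r
```

The dimer building block sits rotated by a fixed offset (default 30°) from
the filament direction, so its orientation relative to the tube axis is
`η = θ + 30°`; at `η = 90°` (`θ = 60°`) the dimer's curved membrane
footprint is aligned with the tube's circumferential curvature.

The elastic energy per unit length assigned to a geometry is

```
E = k_κ (κ − κ₀)² + k_τ (τ − τ₀)² + k_η (η − 90°)²
```

with spontaneous curvature `κ₀` and spontaneous twist `τ₀` (1/nm) and
dimensionless stiffness weights. The predicted helix angle at a given tube
radius is the `θ ∈ [0°, 90°)` minimizing `E`. Three regimes are built in:

- **curvature only** (`k_κ=1, k_τ=k_η=0`): twist elasticity and dimer
  orientation negligible. The minimizer has a closed form,
  `tan θ = √(1/(rκ₀) − 1)` for `r < 1/κ₀` and `θ = 0` otherwise: for tubes
  wider than the preferred wrapping radius `1/κ₀` the spontaneous curvature
  is unreachable (κ ≤ 1/r < κ₀ everywhere), the energy is monotone in κ,
  and the ring maximizes κ — hence the clamp to `θ = 0`. Note the closed
  form is the minimizer of the energy written above; the square root equals
  `tan θ`, not `θ`, and the distinction matters at the ~60° angles narrow
  tubes produce.
- **curvature + twist** (`k_κ=k_τ=1, k_η=0`): the generic continuous-filament
  model, with `τ₀` as a second free parameter.
- **curvature + dimer orientation** (`k_κ=1, k_τ=0, k_η=0.2`): adds a
  preference for the dimer footprint to align perpendicular to the tube
  axis; used with `κ₀` held fixed, so it has no free parameters.

Angles are degrees at every public interface and radians internally. The
unit in which the `(η − 90°)` deviation enters the energy is configurable
(`angle_unit_in_energy`, default radians) because the meaning of the
relative weight `k_η = 0.2` depends on that choice; results for the other
two regimes are unaffected.

## Numerical choices

- `predicted_angle` minimizes `E(θ; r)` on a deterministic 0.01° grid over
  `[0°, 90°)` followed by local refinement (vectorized three-point parabolic
  interpolation; the scalar front end polishes with bounded Brent). Ties
  break toward smaller θ. The grid path is validated against the closed
  form to < 0.01° over the full radius range; the closed form is used as a
  fast path inside fitting loops for the curvature-only regime only.
- Fitting minimizes `Σᵢ (θ_obs,i − θ_pred(rᵢ))²` in squared degrees via
  `scipy.optimize.least_squares` (trf, `κ₀ ≥ 10⁻⁶` bound). Starting values
  are moment-based — the median of `cos²θ_obs/r` for `κ₀` and of
  `sinθ_obs cosθ_obs/r` for `τ₀` — because a cold start such as `τ₀ = 0`
  can park every predicted angle at the 90° boundary, where the loss is
  flat in the parameters and the fit stalls.
- The `κ₀` confidence range is a seeded nonparametric bootstrap: records
  resampled with replacement, each resample refitted, percentile (2.5%,
  97.5%) interval reported. Resamples that are unidentifiable (too few
  distinct radii) are redrawn, up to a bounded retry count. The method is
  assumption-light and exactly reproducible given a seed; measured coverage
  at the default study conditions is ~90% (see `tests/test_acceptance.py`),
  slightly below nominal, as is typical for percentile intervals at n = 50.
- Cylinder fitting (`fit_tube_axis`) profiles the radius out analytically
  and refines (axis point, axis direction) from **three** initializations —
  each principal component of the pooled points — with the direction
  bounded to stay near its initialization. The correct initialization
  depends on the helix angle (a near-axial filament has its axis along the
  largest principal component, a ring along the smallest), and near-planar
  traces also admit degenerate "grazing" cylinders of enormous radius that
  fit within noise. Among candidates whose rms residuals agree within 10%,
  the smallest radius therefore wins; membrane tubes are tens of nm, never
  tens of µm.
- Helix extraction (`helix_from_trace`) unwraps the azimuth assuming
  consecutive trace points advance < 180°, then fits `z = hφ + c` by least
  squares. It requires ≥ 90° of azimuthal extent (configurable): with less,
  the slope — hence pitch and helix angle — is not identifiable. Handedness
  is the sign of `h` and is invariant to the sign chosen for the axis
  direction and to reversing the point order. The per-record radius defaults
  to the tube-wide cylinder fit; the filament's own mean radial distance is
  available (`radius_source="filament"`) because real tubes vary in
  diameter along their length.
- Degenerate inputs raise typed errors (`ValidationError`,
  `FittingError`, `InsufficientExtentError`) rather than returning NaN:
  collinear points, traces under 6 points, rings for handedness (flagged
  `"ring"`, not signed), all-zero elastic weights, < free-parameters + 1
  observations.

## Coat construction

A coat lattice is specified by tube radius, helix angle, arc-length spacing
between dimer centers along a filament, subunit count and number of
parallel filament starts. Per subunit the azimuth advances by
`s·cosθ/r` and the axial coordinate by `s·sinθ`, so consecutive placements
are exactly `s` apart in arc length, and the whole coat obeys the screw
symmetry (rotate by the azimuthal advance, translate by the rise). The
helical family parameters follow as `pitch = 2πr·tanθ`,
`rise = s·sinθ`, `subunits/turn = pitch/rise`; a ring (`θ = 0`) is flagged
with infinite subunits-per-turn (the finite subunits-per-ring count
`2πr/s` is exposed separately). Filament starts are offset uniformly in
azimuth, which makes the perpendicular spacing between neighboring
filaments uniform; explicit phase offsets can override this. Placements are
position + right-handed orthonormal frame (tangent, outward normal,
binormal); dimer internal structure is not modelled. The canonical frame is
the z axis through the origin; exporters apply an optional rigid transform.
PDB export writes CA pseudo-atoms in Å (nm × 10), one chain per filament
(62-chain limit from the PDB chain-ID alphabet), B-factor = subunit index.

## Superposition

`superpose_rmsd` implements the Kabsch/SVD solution of the orthogonal
Procrustes problem with the standard reflection guard (determinant of the
optimal orthogonal matrix checked; the smallest singular direction flipped
if needed, so the returned rotation is always proper). Residues pair by
residue number after an optional integer offset — structures of homologous
proteins are often numbered on different schemes — or by order. The EH
domain exclusion defaults to residues 443–538 and is overrideable. Altloc A
is preferred; insertion codes are rejected because numeric pairing would be
ambiguous. Tests cross-check the rotation against
`scipy.spatial.transform.Rotation.align_vectors` and against a brute-force
search over rotation space on a small instance.

## What the synthetic data emulates — and what it does not

The generators (`simulate.py`) produce every input the pipeline consumes,
as pure functions of (configuration, seed):

- **Angle–radius datasets**: tube radii uniform on 15–70 nm (the range
  where ordered oligomers are observed; a log-uniform option exists for
  robustness checks), true angles from the elastic model, Gaussian noise on
  the angle (default SD 5°; the real measurement error of traced angles is
  unknown — 5° is a realistic figure for hand-traced tomogram filaments,
  chosen once, not a measured value), truncated to [0°, 89.9°]. Truncation
  bias is negligible at the default SD except within ~2σ of the domain
  edges.
- **Helix traces**: uniform arc-length sampling (default 1.5 turns) plus
  isotropic Gaussian positional noise (default 0.5 nm).
- **Coat point clouds**: built-coat placements jittered per filament.

None of this emulates tomographic reality beyond those statistics: no
missing-wedge anisotropy, no orientation-dependent noise, no tube
taper or curvature along the axis, no filament discontinuities, no
mis-tracing outliers. Passing recovery tests therefore show the estimator
chain is consistent and well-calibrated under its own assumptions — not
that those assumptions hold for any particular tomogram.

## Default parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `kappa0` (generator) | 1/68 | 1/nm | spontaneous curvature of the AMPPNP-bound filament |
| `radius_range` | (15, 70) | nm | observed range of ordered-oligomer tubes |
| `n_tubes` | 50 | — | of the order of the measured per-filament dataset |
| `angle_noise_sd` | 5 | deg | plausible tracing error; not a measured value |
| `trace_point_noise_sd` | 0.5 | nm | sub-pixel tracing precision at ~2.6 Å/px |
| `dimer_offset` | 30 | deg | dimer rotation relative to the filament |
| `eta0` | 90 | deg | preferred dimer orientation (perpendicular to axis) |
| `k_eta` | 0.2 | — | fixed-regime weight; η deviation in radians by default |
| `subunit_spacing` | 7 | nm | approximate dimer footprint along the filament |
| bootstrap `n_boot` | 1000 | — | percentile interval stability |

Problem sizes used by the test suite and the acceptance script (50 tubes,
100 seeds or replicates, 200–500 bootstrap resamples, 1000-point radius
grids) were chosen so the full statistical checks run in about a minute
while keeping Monte-Carlo error far below the tolerances being asserted.

## Known limitations

- The energy is per-unit-length and purely local: no membrane deformation
  energy, no thermal fluctuations, no filament–filament interaction term,
  no explanation of how tubes thinner than `1/κ₀⁻¹`-preferred are reached.
- The twist regime's fitted `τ₀` trades off against `κ₀` on narrow radius
  ranges; with data spanning only part of the curve the two-parameter fit
  can be weakly identified.
- Helix extraction assumes a single constant helix per trace; filaments
  that change angle along their length are averaged, not segmented.
- Residue pairing for RMSD is numeric (with offset) or positional; no
  sequence alignment, so comparing structures with insertions requires
  prior renumbering.
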