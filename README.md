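# tubecoat

Elastic filament geometry and coat modelling on membrane tubes.

Dynamin-family proteins such as the EHD ATPases oligomerize into helical
filaments that wrap membrane tubes and adapt to — or generate — membrane
curvature. Cryo-electron tomography yields, for each coated tube, the tube
radius `r` and the filament's helix angle `θ` (its deviation from a simple
ring; 0° = ring, →90° = axial). `tubecoat` turns such measurements into an
estimate of the filament's **spontaneous curvature** `κ₀`, the centerline
curvature at which its bending energy vanishes — equivalently, the inverse
of its preferred wrapping radius.

The package is a library first: import it from Python, or run the short
narrative scripts in `examples/`. A thin `tubecoat` CLI wraps the same
functions for shell use.

## The model

A filament wrapped at constant helix angle on a tube of radius `r` has
curvature and twist

    κ = cos²θ / r        τ = sinθ·cosθ / r

and its dimer subunit is oriented at `η = θ + 30°` to the tube axis. The
filament's elastic energy is

    E = k_κ (κ − κ₀)² + k_τ (τ − τ₀)² + k_η (η − 90°)²

and the observed helix angle at each radius is modelled as the `θ`
minimizing `E`. When twist and dimer terms are negligible
(`k_τ = k_η = 0`) the minimum-energy curve has the closed form

    tan θ(r) = √( 1/(rκ₀) − 1 )   for r < 1/κ₀,   θ = 0 otherwise,

so fitting the measured (r, θ) scatter by least squares estimates `κ₀`
directly. Narrow tubes force large helix angles: at `κ₀ = 1/68 nm⁻¹` the
curve reaches 60° at r = 17 nm and ≈62° at r = 15 nm — and 60° is exactly
where the dimer's curved membrane footprint (`η = 90°`) aligns with the
tube's circumferential curvature.

Also included: measurement of (r, θ) from traced 3D filament coordinates
(least-squares cylinder fit + azimuth-unwrap pitch fit), seeded synthetic
data generators for every input, parametric construction of multi-filament
helical coats (pitch / rise / subunits-per-turn, PDB and CSV export), and a
Kabsch Cα-superposition utility for comparing coordinate models.

## Worked example

```python
from tubecoat import (SimulationConfig, curvature_only_params, fit_spontaneous,
                      kappa0_confidence_range, simulate_angle_radius_dataset)

# 50 tubes on 15-70 nm, angles on the kappa0 = 1/68 curve + 5 deg noise
cfg = SimulationConfig(seed=42, n_tubes=50, kappa0_true=1/68, angle_noise_sd=5.0)
data = simulate_angle_radius_dataset(cfg)

regime = curvature_only_params(kappa0=0.02)   # starting value; kappa0 is fitted
fit = fit_spontaneous(data, regime)
lo, hi = kappa0_confidence_range(data, regime, n_boot=500, seed=42)
print(fit.params.kappa0, (lo, hi))
```

Running `python examples/02_fit_spontaneous_curvature.py` (which does the
above) prints:

```
observations          : 50 filaments
fitted kappa0         : 0.01478 1/nm  (preferred radius 67.6 nm)
95% bootstrap range   : [0.01462, 0.01516] 1/nm
residual sum (deg^2)  : 702.8
```

The fitted spontaneous curvature 0.01478 nm⁻¹ recovers the generating
1/68 = 0.01471 nm⁻¹ well within the bootstrap range; the preferred radius
(~68 nm) is the widest tube the filament wraps without tilting, and the
residual sum is of the order n·σ² expected from the 5° measurement noise.
The other examples cover helix geometry (`01`), trace measurement
(`03`), coat building (`04`), superposition (`05`) and the full
traces→fits pipeline (`06`).

Command-line equivalents:

```sh
tubecoat simulate --seed 42 --n-tubes 50 --out-dir sim
tubecoat fit sim/angle_radius.csv --out-dir fits
tubecoat coat --radius 15 --helix-angle 60 --n-filaments 3 --out coat.pdb
tubecoat rmsd model.pdb crystal.pdb --chain-a A --chain-b A
```

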