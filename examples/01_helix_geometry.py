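"""Differential geometry of a filament wrapped on a membrane tube.

A constant helix on a tube of radius r with reduced pitch h (pitch = 2*pi*h)
has curvature kappa = r/(r^2+h^2), twist tau = h/(r^2+h^2) and helix angle
theta = atan(h/r).  The dimer sits rotated 30 degrees from the filament
direction, so its orientation relative to the tube axis is eta = theta + 30.
"""

from tubecoat import HelixParams, aligned_helix_angle, geometry_from_helix

helix = HelixParams(radius_r=17.0, reduced_pitch_h=17.0 * 3**0.5)  # 60 deg helix
geom = geometry_from_helix(helix)

print(f"tube radius          : {helix.radius_r:.1f} nm")
print(f"pitch                : {helix.pitch:.1f} nm")
print(f"curvature kappa      : {geom.curvature_kappa:.5f} 1/nm")
print(f"twist tau            : {geom.twist_tau:.5f} 1/nm")
print(f"helix angle theta    : {geom.helix_angle_theta:.2f} deg")
print(f"dimer orientation eta: {geom.dimer_orientation_eta:.2f} deg")
print(f"handedness           : {geom.handedness}")
print()
print("At eta = 90 deg the dimer's footprint curvature is aligned with the")
print("tube's circumferential curvature; that happens at helix angle "
      f"{aligned_helix_angle():.1f} deg.")
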