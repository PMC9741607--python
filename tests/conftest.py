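import numpy as np
import pytest

from tubecoat import HelixParams, LatticeSpec, curvature_only_params


@pytest.fixture
def kappa0_paper():
    """Spontaneous curvature of the AMPPNP-bound filament, 1/68 1/nm."""
    return 1.0 / 68.0


@pytest.fixture
def curvature_regime(kappa0_paper):
    return curvature_only_params(kappa0_paper)


@pytest.fixture
def helix_r20_h10():
    return HelixParams(radius_r=20.0, reduced_pitch_h=10.0)


@pytest.fixture
def lattice_60deg():
    return LatticeSpec(
        radius_r=15.0, helix_angle_theta=60.0, subunit_spacing=7.0,
        n_subunits=30, n_filaments=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_pdb(path, coords, chain="A", start_resnum=1, bfac=0.0):
    """Write a minimal PDB of CA pseudo-atoms at the given Angstrom coords."""
    lines = []
    for i, (x, y, z) in enumerate(coords):
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA {chain}{start_resnum + i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00{bfac:6.2f}           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
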