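"""Shared fixtures: small hand-written structure files and synthetic systems.

All fixtures are generated programmatically; coordinates in the PDB/GRO
pair are chosen on the 0.01 Å grid so the two formats encode identical
positions (GRO stores nm to 3 decimals).
"""

import numpy as np
import pytest

import barbend as bb

PDB_3ATOM = """\
ATOM      1  N   ALA A   1      11.100   6.130  -6.500  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.640   6.070  -5.150  1.00  0.00           C
ATOM      3  P   POP M   2       1.000   2.000   3.000  1.00  0.00           P
END
"""

GRO_3ATOM = """\
three-atom fixture t= 0.0
3
    1ALA      N    1   1.110   0.613  -0.650
    1ALA     CA    2   1.164   0.607  -0.515
    2POP      P    3   0.100   0.200   0.300
   5.00000   5.00000   5.00000
"""


@pytest.fixture
def pdb_file(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(PDB_3ATOM)
    return p


@pytest.fixture
def gro_file(tmp_path):
    p = tmp_path / "three.gro"
    p.write_text(GRO_3ATOM)
    return p


@pytest.fixture(scope="session")
def static_dimer():
    """Pseudo-dimer with arms at rest (two identical frames)."""
    spec = bb.DimerSpec(arm_angle_series=np.zeros(2))
    return bb.generate_dimer_trajectory(spec)


@pytest.fixture(scope="session")
def flat_membrane():
    """Noise-free flat phosphorus lattice, default geometry, 3 frames."""
    spec = bb.MembraneSpec(radius_series=[np.inf] * 3, noise_sd=0.0)
    return bb.generate_membrane_trajectory(spec)


@pytest.fixture(scope="session")
def bent_membrane_500():
    """Noise-free membrane bent at R = 500 Å, 5 frames."""
    spec = bb.MembraneSpec(radius_series=[500.0] * 5, noise_sd=0.0)
    return bb.generate_membrane_trajectory(spec)


@pytest.fixture(scope="session")
def flat_bundle():
    """Flat membrane + static dimer combined, aligned-convention layout."""
    n = 3
    mem, _ = bb.generate_membrane_trajectory(
        bb.MembraneSpec(radius_series=[np.inf] * n, noise_sd=0.0))
    dim, _ = bb.generate_dimer_trajectory(
        bb.DimerSpec(arm_angle_series=np.zeros(n)))
    return bb.place_dimer_on_membrane(mem, dim)
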