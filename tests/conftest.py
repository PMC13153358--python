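"""Shared fixtures: a hand-placed synthetic GluA1/A2 tetramer.

The tetramer places landmark, gate and filler Cα atoms at coordinates
chosen by hand, so every distance/area assertion downstream can be
computed directly from this table, independent of the package's own
selection machinery.
"""

import numpy as np
import pytest
import biotite.structure as struc

from amparcore import StructureModel, default_glua1a2_config

# (chain, residue) -> xyz.  Chains A/C carry GluA1 numbering (landmarks
# A737/S631, gates 613/617/621), chains B/D GluA2 numbering (S741/S635,
# gates 617/621/625).  Gate tetrads sit on squares of circumradius 4 at
# z = 0 (T617 level), z = 4 (A621), z = 8 (T625).
_S2 = 4.0 / np.sqrt(2.0)
TETRAMER_COORDS = {
    # D1 landmarks (upper lobes, z = 40)
    ("A", 737): (10.0, 10.0, 40.0),
    ("D", 741): (-2.0, 10.0, 40.0),
    ("B", 741): (-10.0, -10.0, 40.0),
    ("C", 737): (2.0, -10.0, 40.0),
    # D2 landmarks (lower lobes, z = 20)
    ("A", 631): (6.0, 6.0, 20.0),
    ("C", 631): (-6.0, -6.0, 20.0),
    ("B", 635): (-8.0, 8.0, 20.0),
    ("D", 635): (8.0, -8.0, 20.0),
    # gate tetrads: A at 45 deg, B at 135, C at 225, D at 315
    ("A", 613): (_S2, _S2, 0.0), ("B", 617): (-_S2, _S2, 0.0),
    ("C", 613): (-_S2, -_S2, 0.0), ("D", 617): (_S2, -_S2, 0.0),
    ("A", 617): (_S2, _S2, 4.0), ("B", 621): (-_S2, _S2, 4.0),
    ("C", 617): (-_S2, -_S2, 4.0), ("D", 621): (_S2, -_S2, 4.0),
    ("A", 621): (_S2, _S2, 8.0), ("B", 625): (-_S2, _S2, 8.0),
    ("C", 621): (-_S2, -_S2, 8.0), ("D", 625): (_S2, -_S2, 8.0),
}

# Filler Cα atoms so every lobe (d1/d2/lbd) resolves to >= 3 residues per
# chain and the per-chain LBD clouds are rank 3.  GluA1 numbering for A/C,
# GluA2 (+4) for B/D.
_D1_FILL = {"GluA1": (400, 401), "GluA2": (404, 405)}
_D2_FILL = {"GluA1": (700, 701), "GluA2": (704, 705)}
_CHAIN_IDENTITY = {"A": "GluA1", "C": "GluA1", "B": "GluA2", "D": "GluA2"}
_FILL_OFFSETS = [(1.0, 0.0, 2.0), (0.0, 3.0, -1.0)]
_CHAIN_BASE = {"A": (12.0, 12.0, 30.0), "B": (-12.0, 12.0, 30.0),
               "C": (-12.0, -12.0, 30.0), "D": (12.0, -12.0, 30.0)}

for _ch, _ident in _CHAIN_IDENTITY.items():
    bx, by, bz = _CHAIN_BASE[_ch]
    for _res, (ox, oy, oz) in zip(_D1_FILL[_ident], _FILL_OFFSETS):
        TETRAMER_COORDS[(_ch, _res)] = (bx + ox, by + oy, bz + 10 + oz)
    for _res, (ox, oy, oz) in zip(_D2_FILL[_ident], _FILL_OFFSETS):
        TETRAMER_COORDS[(_ch, _res)] = (bx + oy, by + ox, bz - 10 + oz)


def build_tetramer(coords: dict | None = None, label: str = "tetramer") -> StructureModel:
    coords = coords or TETRAMER_COORDS
    keys = sorted(coords)
    n = len(keys)
    arr = struc.AtomArray(n)
    arr.coord = np.array([coords[k] for k in keys], dtype=float)
    arr.chain_id = np.array([k[0] for k in keys])
    arr.res_id = np.array([k[1] for k in keys])
    arr.res_name = np.full(n, "GLY")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    return StructureModel(arr, label)


@pytest.fixture(scope="session")
def tetramer():
    return build_tetramer()


@pytest.fixture(scope="session")
def default_map():
    return default_glua1a2_config()


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus translation (test helper)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return R, t


def transform_model(model: StructureModel, R, t) -> StructureModel:
    atoms = model.atoms.copy()
    atoms.coord = atoms.coord @ R.T + t
    return StructureModel(atoms, model.label + "_moved")
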