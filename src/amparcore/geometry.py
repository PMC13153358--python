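"""Rigid-body superposition and LBD gating metrics.

Three measurements drive the analysis of ligand-binding-domain (LBD)
rearrangements in AMPA-receptor gating:

* landmark Cα–Cα distances between the upper (D1) and lower (D2) clamshell
  lobes, within LBD dimers and across the tetramer diagonals;
* the clamshell-closure / hinge rotation angle α: after superposing two
  functional states on the D1 lobe, the residual optimal rotation of D2;
* the two-fold-symmetry deviation angle β of an LBD dimer: superpose one
  protomer onto the other and measure how far the optimal rotation is from
  a perfect 180° flip, β = |180° − θ|.  β = 0 iff the dimer is exactly
  C2-symmetric over the paired atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .structures import StructureModel, SubunitMap, StructureError, select_calpha

__all__ = [
    "RigidTransform",
    "GeometryReport",
    "superpose",
    "rotation_angle_axis",
    "ca_distance",
    "c2_deviation_beta",
    "lobe_closure_angle",
    "geometry_report",
    "pair_protomer_calphas",
]


@dataclass(frozen=True)
class RigidTransform:
    """Least-squares rigid transform mapping a mobile point cloud onto a target."""

    rotation: np.ndarray       # (3, 3), proper orthogonal
    translation: np.ndarray    # (3,), applied after rotation
    rotation_angle: float      # degrees, in [0, 180]
    rotation_axis: np.ndarray  # unit vector (sign convention: positive angle)
    rmsd_before: float
    rmsd_after: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _as_points(x: Sequence, name: str) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got {pts.shape}")
    return pts


def rotation_angle_axis(rotation: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, [0, 180]) and unit axis of a proper rotation matrix."""
    tr = np.clip((np.trace(rotation) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(tr))
    # Axis from the skew-symmetric part; near 180° fall back to the
    # eigenvector of R with eigenvalue +1.
    w = np.array(
        [
            rotation[2, 1] - rotation[1, 2],
            rotation[0, 2] - rotation[2, 0],
            rotation[1, 0] - rotation[0, 1],
        ]
    )
    norm = np.linalg.norm(w)
    if norm > 1e-8:
        axis = w / norm
    else:
        vals, vecs = np.linalg.eigh((rotation + rotation.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
        axis = axis / np.linalg.norm(axis)
    return float(angle), axis


def superpose(mobile: Sequence, target: Sequence) -> RigidTransform:
    """Optimal (least-squares) superposition of ``mobile`` onto ``target``.

    Kabsch algorithm with a reflection guard; no weighting.  Requires equal
    lengths ≥ 3 and point clouds of rank 3 after centering (a plane is rank
    2 and would leave the out-of-plane rotation undetermined).
    """
    P = _as_points(mobile, "mobile")
    Q = _as_points(target, "target")
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: mobile {P.shape[0]} vs target {Q.shape[0]}")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    for name, X in (("mobile", Pc), ("target", Qc)):
        rank = np.linalg.matrix_rank(X, tol=1e-8 * max(1.0, np.abs(X).max()))
        if rank < 3:
            raise ValueError(f"degenerate {name} cloud: rank {rank} < 3")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    angle, axis = rotation_angle_axis(R)
    rmsd_before = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
    moved = P @ R.T + t
    rmsd_after = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(R, t, angle, axis, rmsd_before, rmsd_after)


def ca_distance(
    model: StructureModel, a: tuple[str, int], b: tuple[str, int]
) -> float:
    """Euclidean Cα–Cα distance in Å between (chain, residue) pairs."""
    pa = select_calpha(model, a[0], [a[1]])[0]
    pb = select_calpha(model, b[0], [b[1]])[0]
    return float(np.linalg.norm(pa - pb))


def c2_deviation_beta(
    protomer1: Sequence, protomer2: Sequence
) -> float:
    """Deviation of a dimer from exact two-fold rotational symmetry, degrees.

    Superposes protomer 1 onto protomer 2 over a 1:1 Cα correspondence and
    returns β = \\|180° − θ\\| where θ is the optimal rotation angle.  An
    exact C2 dimer gives θ = 180° hence β = 0.
    """
    tf = superpose(protomer1, protomer2)
    return float(abs(180.0 - tf.rotation_angle))


def lobe_closure_angle(
    d1_state1: Sequence,
    d2_state1: Sequence,
    d1_state2: Sequence,
    d2_state2: Sequence,
) -> float:
    """Hinge rotation of the D2 lobe between two states of one LBD, degrees.

    The two states are first superposed on their D1 lobes; the returned
    value is the rotation angle of the residual optimal transform carrying
    the state-1 D2 lobe onto the state-2 D2 lobe.  This reports the full
    residual-rotation angle, not a projection onto a hinge plane.
    """
    d2_a = _as_points(d2_state1, "d2_state1")
    d2_b = _as_points(d2_state2, "d2_state2")
    if d2_a.shape != d2_b.shape:
        raise ValueError("D2 lobes must share a residue correspondence")
    align = superpose(d1_state1, d1_state2)
    residual = superpose(align.apply(d2_a), d2_b)
    return float(residual.rotation_angle)


# -- residue pairing for hetero-dimers --------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


def _chain_calpha_table(model: StructureModel, chain: str, residues=None):
    a = model.atoms
    mask = (a.chain_id == chain) & (a.atom_name == "CA")
    res_ids = a.res_id[mask]
    res_names = a.res_name[mask]
    coords = a.coord[mask]
    order = np.argsort(res_ids)
    res_ids, res_names, coords = res_ids[order], res_names[order], coords[order]
    if residues is not None:
        keep = np.isin(res_ids, list(residues))
        res_ids, res_names, coords = res_ids[keep], res_names[keep], coords[keep]
    return res_ids, res_names, coords


def pair_protomer_calphas(
    model: StructureModel,
    chain1: str,
    chain2: str,
    residues1=None,
    residues2=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned Cα coordinate pairs for two (possibly homologous) chains.

    Identical residue numberings are paired directly; otherwise the two
    sequences are globally aligned (BLOSUM62) and only aligned, non-gap Cα
    pairs are kept.  Raises :class:`StructureError` if fewer than 3 pairs
    survive.
    """
    ids1, names1, xyz1 = _chain_calpha_table(model, chain1, residues1)
    ids2, names2, xyz2 = _chain_calpha_table(model, chain2, residues2)
    if len(ids1) == 0 or len(ids2) == 0:
        raise StructureError(
            f"no CA atoms for pairing in chains {chain1!r}/{chain2!r}"
        )
    common = sorted(set(ids1) & set(ids2))
    if len(common) == len(ids1) == len(ids2):
        i1 = {int(r): i for i, r in enumerate(ids1)}
        i2 = {int(r): i for i, r in enumerate(ids2)}
        p1 = np.array([xyz1[i1[r]] for r in common])
        p2 = np.array([xyz2[i2[r]] for r in common])
    else:
        import biotite.sequence as seq
        import biotite.sequence.align as align

        s1 = seq.ProteinSequence("".join(_THREE_TO_ONE.get(n, "X") for n in names1))
        s2 = seq.ProteinSequence("".join(_THREE_TO_ONE.get(n, "X") for n in names2))
        matrix = align.SubstitutionMatrix.std_protein_matrix()
        ali = align.align_optimal(s1, s2, matrix, gap_penalty=(-10, -1))[0]
        trace = ali.trace
        keep = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
        p1 = xyz1[trace[keep, 0]]
        p2 = xyz2[trace[keep, 1]]
    if len(p1) < 3:
        raise StructureError(
            f"chains {chain1!r}/{chain2!r}: only {len(p1)} aligned CA pairs"
        )
    return p1, p2


# -- full report -------------------------------------------------------------

@dataclass
class GeometryReport:
    """All LBD gating metrics for one structure, distances in Å, angles in °."""

    label: str
    state: str
    d1_d1: dict[str, float]          # dimer ("A/D", "B/C") -> D1 landmark dist
    d2_d2: dict[str, float]          # dimer -> D2 landmark dist
    diagonal_ac: float               # A/C D2-landmark separation
    diagonal_bd: float               # B/D D2-landmark separation
    beta: dict[str, float]           # dimer -> two-fold deviation, degrees
    beta_mean: float
    closure_alpha: dict[str, float] | None  # position -> closure angle vs reference

    def as_dict(self) -> dict:
        return asdict(self)


_DIMERS = (("A", "D"), ("B", "C"))


def _dimer_beta(model: StructureModel, smap: SubunitMap, pos1: str, pos2: str) -> float:
    p1, p2 = pair_protomer_calphas(
        model,
        smap.chain(pos1),
        smap.chain(pos2),
        residues1=smap.lobe_residues(pos1, "lbd"),
        residues2=smap.lobe_residues(pos2, "lbd"),
    )
    return c2_deviation_beta(p1, p2)


def geometry_report(
    model: StructureModel,
    smap: SubunitMap,
    reference: StructureModel | None = None,
    reference_map: SubunitMap | None = None,
    state: str = "",
) -> GeometryReport:
    """Populate every gating metric for one structure.

    ``reference`` (e.g. the closed-state model) is needed only for the
    clamshell-closure angle α; without it α is reported as ``None``.
    Landmark residues default to A737/S631 (GluA1) and S741/S635 (GluA2)
    from the packaged configuration.
    """
    d1_d1, d2_d2, beta = {}, {}, {}
    for pos1, pos2 in _DIMERS:
        key = f"{pos1}/{pos2}"
        d1_d1[key] = ca_distance(
            model,
            (smap.chain(pos1), smap.landmark(pos1, "d1")),
            (smap.chain(pos2), smap.landmark(pos2, "d1")),
        )
        d2_d2[key] = ca_distance(
            model,
            (smap.chain(pos1), smap.landmark(pos1, "d2")),
            (smap.chain(pos2), smap.landmark(pos2, "d2")),
        )
        beta[key] = _dimer_beta(model, smap, pos1, pos2)
    diagonal_ac = ca_distance(
        model,
        (smap.chain("A"), smap.landmark("A", "d2")),
        (smap.chain("C"), smap.landmark("C", "d2")),
    )
    diagonal_bd = ca_distance(
        model,
        (smap.chain("B"), smap.landmark("B", "d2")),
        (smap.chain("D"), smap.landmark("D", "d2")),
    )
    closure = None
    if reference is not None:
        rmap = reference_map or smap
        closure = {}
        for pos in "ABCD":
            try:
                d1_res = smap.lobe_residues(pos, "d1")
                d2_res = smap.lobe_residues(pos, "d2")
                d1_ref = select_calpha(
                    reference, rmap.chain(pos), [r - smap.offset(pos) + rmap.offset(pos) for r in d1_res]
                )
                d2_ref = select_calpha(
                    reference, rmap.chain(pos), [r - smap.offset(pos) + rmap.offset(pos) for r in d2_res]
                )
                d1_mod = select_calpha(model, smap.chain(pos), d1_res)
                d2_mod = select_calpha(model, smap.chain(pos), d2_res)
            except StructureError as exc:
                warnings.warn(f"closure angle unavailable at position {pos}: {exc}")
                continue
            closure[pos] = lobe_closure_angle(d1_ref, d2_ref, d1_mod, d2_mod)
    return GeometryReport(
        label=model.label,
        state=state,
        d1_d1={k: round(v, 1) for k, v in d1_d1.items()},
        d2_d2={k: round(v, 1) for k, v in d2_d2.items()},
        diagonal_ac=round(diagonal_ac, 1),
        diagonal_bd=round(diagonal_bd, 1),
        beta={k: round(v, 1) for k, v in beta.items()},
        beta_mean=round(float(np.mean(list(beta.values()))), 1),
        closure_alpha=(
            {k: round(v, 1) for k, v in closure.items()} if closure is not None else None
        ),
    )
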