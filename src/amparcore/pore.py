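"""Sphere-probe pore-radius profiling along a channel axis.

For every slice along the axis, the profiler finds the in-plane point
maximizing the clearance to the nearest atom surface (atom centre distance
minus its van der Waals radius) — the radius of the largest sphere
inscribed in the pore with its centre on that plane.  The search is
deterministic: a coarse in-plane grid seeded from the previous slice's
centre, refined by Nelder–Mead.  This is a reproducible dialect of the
classic sphere-probe profilers, which use simulated annealing instead.

Also provided: cross-pore Cα distances between diagonal subunits and the
√area of the quadrilateral spanned by a gate residue's four Cα atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .structures import StructureModel, SubunitMap, select_calpha

__all__ = [
    "RadiusSet",
    "BONDI",
    "AMBER_UNITED",
    "PoreProfile",
    "compute_pore_profile",
    "min_gate_radius",
    "cross_pore_distance",
    "gate_cross_sqrt_area",
]


@dataclass(frozen=True)
class RadiusSet:
    """Element → van der Waals radius map (Å) with a declared fallback."""

    radii: dict
    name: str = "custom"
    fallback: float = 1.5

    def __post_init__(self) -> None:
        bad = {e: r for e, r in self.radii.items() if r <= 0}
        if bad or self.fallback <= 0:
            raise ValueError(f"vdW radii must be positive: {bad or self.fallback}")

    def lookup(self, elements: np.ndarray) -> np.ndarray:
        out = np.empty(len(elements), dtype=float)
        unknown = set()
        for i, e in enumerate(elements):
            key = str(e).strip().capitalize()
            r = self.radii.get(key)
            if r is None:
                unknown.add(key)
                r = self.fallback
            out[i] = r
        if unknown:
            warnings.warn(
                f"{self.name}: unknown elements {sorted(unknown)} assigned "
                f"fallback radius {self.fallback} Å"
            )
        return out

    def inflated(self, delta: float) -> "RadiusSet":
        return RadiusSet(
            {e: r + delta for e, r in self.radii.items()},
            name=f"{self.name}+{delta}",
            fallback=self.fallback + delta,
        )


BONDI = RadiusSet(
    {
        "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
        "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Na": 2.27, "K": 2.75,
        "Mg": 1.73, "Ca": 2.31, "Zn": 1.39, "Fe": 1.40, "Se": 1.90,
    },
    name="bondi",
)

# AMBER-derived united-atom-flavoured set (heavier H, slightly larger C)
AMBER_UNITED = RadiusSet(
    {
        "H": 1.00, "C": 1.85, "N": 1.75, "O": 1.60, "S": 2.00, "P": 2.10,
        "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Na": 1.87, "K": 2.66,
        "Mg": 1.36, "Ca": 1.71, "Zn": 1.10, "Fe": 1.20, "Se": 2.00,
    },
    name="amber",
)


@dataclass
class PoreProfile:
    """Per-slice pore centre and maximal inscribed-sphere radius."""

    origin: np.ndarray      # axis origin, lab frame
    direction: np.ndarray   # unit axis vector
    z: np.ndarray           # axial coordinate of each slice, Å
    centers: np.ndarray     # (n, 3) lab-frame pore centres
    radius: np.ndarray      # (n,) Å, capped at `cap`
    capped: np.ndarray      # (n,) bool
    cap: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z,
                "x_center": self.centers[:, 0],
                "y_center": self.centers[:, 1],
                "z_center": self.centers[:, 2],
                "radius": self.radius,
                "capped": self.capped,
            }
        )


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _resolve_axis(model, axis, smap):
    if isinstance(axis, str) and axis == "z":
        return np.zeros(3), np.array([0.0, 0.0, 1.0])
    if isinstance(axis, str) and axis == "auto":
        if smap is None:
            raise ValueError(
                "axis='auto' needs a SubunitMap (gate-residue tetrads define "
                "the pore axis); otherwise pass an explicit (origin, direction)"
            )
        tetrads = []
        for label in ("T617", "T625"):
            pts = [
                select_calpha(model, smap.chain(p), [smap.gate_residue(p, label)])[0]
                for p in "ABCD"
            ]
            tetrads.append(np.mean(pts, axis=0))
        direction = tetrads[1] - tetrads[0]
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            raise ValueError("gate tetrads coincide; supply an explicit axis")
        return np.mean(tetrads, axis=0), direction / norm
    origin, direction = axis
    direction = np.asarray(direction, dtype=float)
    return np.asarray(origin, dtype=float), direction / np.linalg.norm(direction)


def compute_pore_profile(
    model: StructureModel,
    axis="z",
    z_range: tuple[float, float] | None = None,
    step: float = 0.5,
    radii: RadiusSet = BONDI,
    cap: float = 10.0,
    search_radius: float = 15.0,
    grid_step: float = 0.5,
    grid_extent: float = 5.0,
    continuity_bound: float = 2.0,
    exclude_water: bool = True,
) -> PoreProfile:
    """Slice-wise maximal inscribed-sphere radius along the channel axis.

    ``axis`` is ``"z"`` (lab z through the origin), ``"auto"`` (from the
    gate-residue tetrads of a supplied ``smap``), or an explicit
    ``(origin, direction)`` pair passed as a tuple.  Slices with no atoms
    inside the search cylinder are reported at the ``cap`` radius with the
    ``capped`` flag set.

    The first slice is searched over the full in-plane grid; every later
    slice is searched within ``continuity_bound`` Å of the previous centre,
    which keeps the probe inside the pore instead of letting it escape
    around the outside of the protein.
    """
    smap = None
    if isinstance(axis, tuple) and len(axis) == 2 and isinstance(axis[1], SubunitMap):
        axis, smap = axis
    if isinstance(axis, SubunitMap):
        smap, axis = axis, "auto"
    origin, direction = _resolve_axis(model, axis, smap)
    u, v = _axis_frame(direction)

    atoms = model.atoms
    if exclude_water:
        from .structures import _WATER_NAMES

        keep = ~np.isin(atoms.res_name, list(_WATER_NAMES))
        atoms = atoms[keep]
    coords = atoms.coord
    vdw = radii.lookup(atoms.element)
    rel = coords - origin
    axial = rel @ direction
    radial = np.linalg.norm(rel - np.outer(axial, direction), axis=1)
    in_cyl = radial <= search_radius
    coords, vdw, axial = coords[in_cyl], vdw[in_cyl], axial[in_cyl]
    if z_range is None:
        if axial.size == 0:
            raise ValueError("no atoms inside the search cylinder; supply z_range")
        z_range = (float(axial.min()), float(axial.max()))
    z_slices = np.arange(z_range[0], z_range[1] + 0.5 * step, step)
    max_r = float(vdw.max()) if vdw.size else 0.0

    def make_grid(extent: float, spacing: float) -> np.ndarray:
        g = np.arange(-extent, extent + 0.5 * spacing, spacing)
        gu, gv = np.meshgrid(g, g)
        return np.column_stack([gu.ravel(), gv.ravel()])

    full_grid = make_grid(grid_extent, grid_step)
    local_grid = make_grid(continuity_bound, min(grid_step, continuity_bound / 4))

    centers = np.empty((z_slices.size, 3))
    radius = np.empty(z_slices.size)
    capped = np.zeros(z_slices.size, dtype=bool)
    prev_ab: np.ndarray | None = None

    for k, zk in enumerate(z_slices):
        sel = np.abs(axial - zk) <= cap + max_r
        pts = coords[sel]
        rads = vdw[sel]
        base = origin + zk * direction
        if pts.shape[0] == 0:
            centers[k] = base
            radius[k] = cap
            capped[k] = True
            prev_ab = None
            continue

        def clearance(ab):
            p = base + ab[0] * u + ab[1] * v
            return np.min(np.linalg.norm(pts - p, axis=1) - rads)

        if prev_ab is None:
            cand = full_grid
            lo = np.array([-grid_extent, -grid_extent])
            hi = np.array([grid_extent, grid_extent])
        else:
            cand = prev_ab[None, :] + local_grid
            lo = prev_ab - continuity_bound
            hi = prev_ab + continuity_bound
        p_all = base + cand[:, 0:1] * u + cand[:, 1:2] * v
        d = np.linalg.norm(p_all[:, None, :] - pts[None, :, :], axis=2) - rads
        scores = d.min(axis=1)
        ab0 = cand[int(np.argmax(scores))]
        res = optimize.minimize(
            lambda ab: -clearance(ab),
            ab0,
            method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        ab = res.x if -res.fun >= scores.max() else ab0
        r = clearance(ab)
        centers[k] = base + ab[0] * u + ab[1] * v
        if r >= cap:
            radius[k] = cap
            capped[k] = True
        else:
            radius[k] = max(r, 1e-6)
        prev_ab = ab
    return PoreProfile(origin, direction, z_slices, centers, radius, capped, cap)


def min_gate_radius(
    profile: PoreProfile, z_window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """(z, radius) of the narrowest slice in a window; ties go to smaller z."""
    if z_window is None:
        sel = np.ones(profile.z.size, dtype=bool)
    else:
        sel = (profile.z >= z_window[0]) & (profile.z <= z_window[1])
    if not np.any(sel):
        raise ValueError(f"window {z_window} does not overlap the profile")
    zw = profile.z[sel]
    rw = profile.radius[sel]
    i = int(np.argmin(rw))  # argmin returns the first (smallest z) on ties
    return float(zw[i]), float(rw[i])


def cross_pore_distance(
    model: StructureModel,
    smap: SubunitMap,
    residue_label: str,
    positions: tuple[str, str] = ("B", "D"),
) -> float:
    """Cα–Cα distance of a gate residue across two subunit positions, Å."""
    pts = [
        select_calpha(model, smap.chain(p), [smap.gate_residue(p, residue_label)])[0]
        for p in positions
    ]
    return float(np.linalg.norm(pts[0] - pts[1]))


def gate_cross_sqrt_area(
    model_or_points, smap: SubunitMap | None = None, residue_label: str | None = None
) -> float:
    """√area (Å) of the quadrilateral of a gate residue's four Cα atoms.

    Points are projected onto their best-fit plane, ordered by angle about
    the centroid, and the planar polygon area evaluated by the shoelace
    formula.  Accepts either ``(model, smap, residue_label)`` or a raw
    (4, 3) coordinate array.
    """
    if isinstance(model_or_points, StructureModel):
        pts = np.array(
            [
                select_calpha(
                    model_or_points, smap.chain(p), [smap.gate_residue(p, residue_label)]
                )[0]
                for p in "ABCD"
            ]
        )
    else:
        pts = np.asarray(model_or_points, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError(f"need exactly 4 points, got {pts.shape}")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("gate quadrilateral is degenerate (collinear points)")
    plane = centered @ vt[:2].T  # in-plane 2-D coordinates
    order = np.argsort(np.arctan2(plane[:, 1], plane[:, 0]))
    q = plane[order]
    x, y = q[:, 0], q[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0:
        raise ValueError("gate quadrilateral has zero area")
    return float(np.sqrt(area))
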