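"""Synthetic fixtures with machine-readable ground truth.

Every downstream stage can be tested without downloads:

* C2-symmetric LBD-dimer point clouds with a controllable injected
  asymmetry rotation, carrying an independently computed quaternion oracle
  for the two-fold-deviation angle β;
* cylindrical atom tubes (optionally constricted) whose minimal pore
  radius is known analytically;
* water trajectories with scripted boundary crossings and a ground-truth
  event list;
* noisy current traces generated from the kinetic equations used in the
  fits they exercise.

Ground truth is always computed independently of the code path under test
(e.g. β by quaternion composition, never by superposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .structures import StructureModel
from .hydration import Trajectory
from .kinetics import CurrentTrace

__all__ = [
    "C2DimerFixture",
    "PoreTubeFixture",
    "WaterTrajectoryFixture",
    "TraceFixture",
    "make_c2_dimer",
    "make_pore_tube",
    "make_water_trajectory",
    "make_current_trace",
    "quat_from_axis_angle",
    "quat_multiply",
    "composed_rotation_beta",
]


# -- quaternion oracle -------------------------------------------------------

def quat_from_axis_angle(axis, angle_deg: float) -> np.ndarray:
    """Unit quaternion (w, x, y, z) for a rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = np.radians(angle_deg) / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2 (apply q2 first, then q1)."""
    w1, v1 = q1[0], q1[1:]
    w2, v2 = q2[0], q2[1:]
    w = w1 * w2 - v1 @ v2
    v = w1 * v2 + w2 * v1 + np.cross(v1, v2)
    return np.concatenate([[w], v])


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def composed_rotation_beta(deviation_deg: float, axis_choice: str) -> float:
    """Oracle β for a 180° flip composed with an extra rotation.

    The composed rotation R_dev · Rz(180°) has total angle θ = 2·acos(|w|)
    from its unit quaternion; β = |180° − θ|.  For a deviation about the
    flip axis itself the angles add (β = deviation); for a perpendicular
    deviation the composition is again a 180° rotation about a tilted
    axis, so β = 0.
    """
    q180 = quat_from_axis_angle([0, 0, 1], 180.0)
    axis = [0, 0, 1] if axis_choice == "parallel" else [1, 0, 0]
    qdev = quat_from_axis_angle(axis, deviation_deg)
    q = quat_multiply(qdev, q180)
    theta = 2.0 * np.degrees(np.arccos(np.clip(abs(q[0]), -1.0, 1.0)))
    return float(abs(180.0 - theta))


# -- C2 dimer ----------------------------------------------------------------

def _pseudo_ca_model(
    chunks: list[tuple[str, np.ndarray]], label: str, element: str = "C"
) -> StructureModel:
    n = sum(len(xyz) for _, xyz in chunks)
    arr = struc.AtomArray(n)
    coord, chain, resid = [], [], []
    for ch, xyz in chunks:
        coord.append(xyz)
        chain.extend([ch] * len(xyz))
        resid.extend(range(1, len(xyz) + 1))
    arr.coord = np.vstack(coord).astype(float)
    arr.chain_id = np.array(chain)
    arr.res_id = np.array(resid)
    arr.res_name = np.full(n, "GLY")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, element)
    arr.hetero = np.zeros(n, dtype=bool)
    return StructureModel(arr, label)


@dataclass(frozen=True)
class C2DimerFixture:
    model: StructureModel          # chain A = protomer 1, chain B = protomer 2
    beta_oracle: float             # degrees, from quaternion composition
    rotation: np.ndarray           # the composed 3x3 rotation applied
    protomer1: np.ndarray
    protomer2: np.ndarray


def make_c2_dimer(
    n_points: int,
    deviation_deg: float,
    axis_choice: str = "parallel",
    seed: int = 0,
    max_attempts: int = 20,
) -> C2DimerFixture:
    """Dimer point cloud: protomer 2 = Rdev · Rz(180°) applied to protomer 1.

    Both rotations act about the origin (the dimer's symmetry point); the
    protomer-1 cloud is placed off-axis so the flip is non-trivial.  The
    recorded oracle β comes from quaternion composition, independent of any
    superposition code.
    """
    if n_points < 4:
        raise ValueError(f"n_points must be >= 4, got {n_points}")
    if not 0 <= deviation_deg < 90:
        raise ValueError(f"deviation_deg must be in [0, 90), got {deviation_deg}")
    if axis_choice not in ("parallel", "perpendicular"):
        raise ValueError(f"axis_choice must be parallel|perpendicular, got {axis_choice}")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        p1 = rng.normal(loc=(9.0, 3.0, 4.0), scale=3.0, size=(n_points, 3))
        centered = p1 - p1.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-6) == 3:
            break
    else:
        raise RuntimeError(f"could not draw a rank-3 cloud in {max_attempts} attempts")
    q180 = quat_from_axis_angle([0, 0, 1], 180.0)
    axis = [0, 0, 1] if axis_choice == "parallel" else [1, 0, 0]
    qdev = quat_from_axis_angle(axis, deviation_deg)
    R = _quat_to_matrix(quat_multiply(qdev, q180))
    p2 = p1 @ R.T
    model = _pseudo_ca_model(
        [("A", p1), ("B", p2)], label=f"c2dimer_dev{deviation_deg}_{axis_choice}"
    )
    return C2DimerFixture(
        model=model,
        beta_oracle=composed_rotation_beta(deviation_deg, axis_choice),
        rotation=R,
        protomer1=p1,
        protomer2=p2,
    )


# -- pore tube ---------------------------------------------------------------

@dataclass(frozen=True)
class PoreTubeFixture:
    model: StructureModel
    atom_radius: float
    tube_radius: float
    ring_z: np.ndarray
    ring_radii: np.ndarray
    min_pore_radius: float          # analytic: min over rings of (ring R - atom r)
    constriction_z: float | None
    n_atoms: int

    @property
    def radius_set(self):
        from .pore import RadiusSet

        return RadiusSet({"C": self.atom_radius}, name="tube-fixture")


def make_pore_tube(
    tube_radius: float,
    length: float = 30.0,
    atom_radius: float = 1.7,
    ring_spacing: float = 1.0,
    constriction: tuple[float, float] | None = None,
    atoms_per_ring: int = 12,
) -> PoreTubeFixture:
    """Rings of pseudo-atoms on a cylinder about z, optionally constricted.

    The analytic minimal pore radius is min over rings of
    (ring radius − atom radius): on the axis at a ring's z the nearest
    atom surface is exactly that far away, and the ring spacing is chosen
    so neighbouring rings do not cut further in.
    """
    if not tube_radius > atom_radius > 0:
        raise ValueError(
            f"need tube_radius > atom_radius > 0, got {tube_radius}, {atom_radius}"
        )
    ring_z = np.arange(-length / 2.0, length / 2.0 + 0.5 * ring_spacing, ring_spacing)
    ring_radii = np.full(ring_z.size, float(tube_radius))
    constr_z = None
    if constriction is not None:
        cz, cr = constriction
        if cr <= atom_radius:
            raise ValueError(
                f"constriction radius {cr} must exceed atom radius {atom_radius}"
            )
        k = int(np.argmin(np.abs(ring_z - cz)))
        ring_radii[k] = cr
        constr_z = float(ring_z[k])
    angles = np.linspace(0.0, 2 * np.pi, atoms_per_ring, endpoint=False)
    coords = []
    for z, r in zip(ring_z, ring_radii):
        ring = np.column_stack(
            [r * np.cos(angles), r * np.sin(angles), np.full(atoms_per_ring, z)]
        )
        coords.append(ring)
    xyz = np.vstack(coords)
    # one chain, sequential residues, so the uniqueness invariant holds
    n = xyz.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = xyz
    arr.chain_id = np.full(n, "T")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "TUB")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.ones(n, dtype=bool)
    model = StructureModel(arr, label="pore-tube")
    return PoreTubeFixture(
        model=model,
        atom_radius=float(atom_radius),
        tube_radius=float(tube_radius),
        ring_z=ring_z,
        ring_radii=ring_radii,
        min_pore_radius=float(ring_radii.min() - atom_radius),
        constriction_z=constr_z,
        n_atoms=n,
    )


# -- water trajectory --------------------------------------------------------

@dataclass(frozen=True)
class WaterTrajectoryFixture:
    trajectory: Trajectory              # gate tetrads + water oxygens
    z: np.ndarray                       # (n_frames, n_waters) water axial coords
    water_ids: np.ndarray
    slab: tuple[float, float]
    events: pd.DataFrame                # ground-truth crossing list
    dt_ns: float


def make_water_trajectory(
    n_waters: int,
    n_frames: int,
    crossing_script: list[tuple[int, int, str]] | None = None,
    slab: tuple[float, float] = (0.0, 10.0),
    seed: int = 0,
    dt_ns: float = 0.1,
    transit_frames: int = 10,
    jitter_sd: float = 0.5,
    margin: float = 2.0,
) -> WaterTrajectoryFixture:
    """Waters jittering on one side of the gate slab plus scripted crossings.

    Each ``(water_id, start_frame, direction)`` script entry moves that
    water monotonically from beyond one boundary to beyond the other over
    ``transit_frames`` frames.  Unscripted waters take reflected Gaussian
    steps (σ = ``jitter_sd``/frame) inside a band that keeps them clear of
    the far boundary, so the ground-truth event list is exactly the script.
    """
    z_lo, z_hi = slab
    if not z_lo < z_hi:
        raise ValueError(f"slab must satisfy z_lo < z_hi, got {slab}")
    script = list(crossing_script or [])
    windows: dict[int, list[tuple[int, int, str]]] = {}
    for wid, start, direction in script:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be up|down, got {direction!r}")
        if not 0 <= wid < n_waters:
            raise ValueError(f"water_id {wid} outside [0, {n_waters})")
        end = start + transit_frames
        if start < 0 or end >= n_frames:
            raise ValueError(
                f"script window [{start}, {end}] does not fit in {n_frames} frames"
            )
        for s0, e0, _ in windows.get(wid, []):
            if start <= e0 and s0 <= end:
                raise ValueError(f"overlapping scripts for water {wid}")
        windows.setdefault(wid, []).append((start, end, direction))
    for wid, entries in windows.items():
        entries.sort()
        for (s0, e0, d0), (s1, e1, d1) in zip(entries, entries[1:]):
            if d0 == d1:
                raise ValueError(
                    f"water {wid}: consecutive same-direction scripts would "
                    f"require a teleport across the slab; alternate directions"
                )

    rng = np.random.default_rng(seed)
    z = np.empty((n_frames, n_waters))
    scripted = set(windows)
    for w in range(n_waters):
        if w in scripted:
            entries = sorted(windows[w])
            # start on the entry side of the first scripted crossing
            first_dir = entries[0][2]
            cur = z_hi + margin if first_dir == "down" else z_lo - margin
            traj = np.full(n_frames, cur)
            for start, end, direction in entries:
                a = z_hi + margin if direction == "down" else z_lo - margin
                b = z_lo - margin if direction == "down" else z_hi + margin
                traj[start:end + 1] = np.linspace(a, b, transit_frames + 1)
                traj[end + 1:] = b
            z[:, w] = traj
        else:
            below = w % 2 == 0
            band = (
                (z_lo - 8.0, z_lo - 1.0) if below else (z_hi + 1.0, z_hi + 8.0)
            )
            steps = rng.normal(0.0, jitter_sd, n_frames)
            pos = np.empty(n_frames)
            cur = float(rng.uniform(*band))
            for f in range(n_frames):
                cur = cur + steps[f]
                # reflect into the band
                lo, hi = band
                while cur < lo or cur > hi:
                    if cur < lo:
                        cur = 2 * lo - cur
                    if cur > hi:
                        cur = 2 * hi - cur
                pos[f] = cur
            z[:, w] = pos

    water_ids = np.arange(n_waters)
    events = pd.DataFrame(
        [
            {
                "water_id": wid,
                "entry_frame": start,
                "exit_frame": start + transit_frames,
                "direction": direction,
            }
            for wid, entries in sorted(windows.items())
            for (start, end, direction) in sorted(entries)
        ],
        columns=["water_id", "entry_frame", "exit_frame", "direction"],
    )

    # assemble a multi-model structure: two gate tetrads + water oxygens
    from .structures import default_glua1a2_config

    smap = default_glua1a2_config()
    gate_chunks = []
    gate_angles = np.radians([0, 90, 180, 270])
    for label, level in (("T617", z_lo), ("T625", z_hi)):
        for pos, ang in zip("ABCD", gate_angles):
            gate_chunks.append(
                (smap.chain(pos), smap.gate_residue(pos, label),
                 np.array([5 * np.cos(ang), 5 * np.sin(ang), level]))
            )
    n_gate = len(gate_chunks)
    n_total = n_gate + n_waters
    template = struc.AtomArray(n_total)
    template.chain_id = np.array(
        [c for c, _, _ in gate_chunks] + ["W"] * n_waters
    )
    template.res_id = np.array(
        [r for _, r, _ in gate_chunks] + list(1000 + water_ids)
    )
    template.res_name = np.array(["THR"] * n_gate + ["HOH"] * n_waters)
    template.atom_name = np.array(["CA"] * n_gate + ["O"] * n_waters)
    template.element = np.array(["C"] * n_gate + ["O"] * n_waters)
    template.hetero = np.array([False] * n_gate + [True] * n_waters)
    coords = np.empty((n_frames, n_total, 3))
    gate_xyz = np.array([xyz for _, _, xyz in gate_chunks])
    coords[:, :n_gate, :] = gate_xyz[None, :, :]
    coords[:, n_gate:, 0] = 1.0
    coords[:, n_gate:, 1] = -1.0
    coords[:, n_gate:, 2] = z
    stack = struc.from_template(template, coords)
    traj = Trajectory(stack, dt_ns=dt_ns, label="synthetic-waters")
    return WaterTrajectoryFixture(
        trajectory=traj,
        z=z,
        water_ids=water_ids,
        slab=(z_lo, z_hi),
        events=events,
        dt_ns=dt_ns,
    )


# -- current traces ----------------------------------------------------------

@dataclass(frozen=True)
class TraceFixture:
    kind: str
    params: dict
    traces: list          # CurrentTrace objects (per interval for envelopes)
    envelope_t: np.ndarray | None = None
    envelope_residual: np.ndarray | None = None      # literal-equation values
    envelope_conditioning: np.ndarray | None = None  # normalized to cond. peak

    @property
    def trace(self) -> CurrentTrace:
        return self.traces[0]


def _noisy(y: np.ndarray, noise_sd: float, scale: float, rng) -> np.ndarray:
    if noise_sd == 0:
        return y
    return y + rng.normal(0.0, noise_sd * scale, y.shape)


def make_current_trace(
    kind: str,
    params: dict | None = None,
    noise_sd: float = 0.0,
    dt: float = 0.1,
    seed: int = 0,
) -> TraceFixture:
    """Noiseless kinetic curves plus additive Gaussian noise at ``noise_sd``
    (a fraction of the peak).

    Kinds and their parameters (defaults reflect GluA1/A2 whole-cell values
    at −60 mV):

    * ``desensitization``: ``tau`` (ms, 7.64), ``t_app`` (1000), ``t_pre``
      (10), ``peak`` (1), ``steady_state`` (0), ``inward`` (True);
    * ``deactivation``: ``tau`` (3.45), ``t_app`` (2), ``t_pre`` (10),
      ``t_post`` (30), ``peak``, ``inward``;
    * ``recovery_envelope``: ``intervals`` (ms), ``tau_recdes`` (75),
      ``m`` (1.02), ``i_max`` (30), ``tau_des``, ``cond_ms`` (100),
      ``test_ms`` (10), ``peak``; emits both the envelope points of the
      recovery equation and full two-pulse traces;
    * ``steady_state_pair``: ``ratio`` (0.032), ``tau``, ``peak``; returns
      the Glu trace and a CTZ (non-desensitizing) trace.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)

    def check_tau(tau):
        if tau <= 0:
            raise ValueError(f"time constant must be positive, got {tau}")

    if kind == "desensitization":
        tau = p.get("tau", 7.64)
        check_tau(tau)
        t_app, t_pre = p.get("t_app", 1000.0), p.get("t_pre", 10.0)
        peak, ss = p.get("peak", 1.0), p.get("steady_state", 0.0)
        sgn = -1.0 if p.get("inward", True) else 1.0
        t = np.arange(0.0, t_pre + t_app + 0.5 * dt, dt)
        y = np.zeros_like(t)
        in_app = t >= t_pre
        y[in_app] = ss + (peak - ss) * np.exp(-(t[in_app] - t_pre) / tau)
        y = sgn * _noisy(y, noise_sd, peak, rng)
        trace = CurrentTrace(
            t, y, {"application": (t_pre, t_pre + t_app)}, label="des"
        )
        return TraceFixture(kind, {"tau": tau, "peak": peak, "steady_state": ss}, [trace])

    if kind == "deactivation":
        tau = p.get("tau", 3.45)
        check_tau(tau)
        t_app, t_pre, t_post = p.get("t_app", 2.0), p.get("t_pre", 10.0), p.get("t_post", 30.0)
        peak = p.get("peak", 1.0)
        sgn = -1.0 if p.get("inward", True) else 1.0
        t = np.arange(0.0, t_pre + t_app + t_post + 0.5 * dt, dt)
        y = np.zeros_like(t)
        t_off = t_pre + t_app
        y[(t >= t_pre) & (t <= t_off)] = peak
        after = t > t_off
        y[after] = peak * np.exp(-(t[after] - t_off) / tau)
        y = sgn * _noisy(y, noise_sd, peak, rng)
        trace = CurrentTrace(t, y, {"application": (t_pre, t_off)}, label="deact")
        return TraceFixture(kind, {"tau": tau, "peak": peak}, [trace])

    if kind == "recovery_envelope":
        from .kinetics import hh_recovery_model

        intervals = np.asarray(
            p.get("intervals", [10, 20, 50, 100, 200, 400]), dtype=float
        )
        tau_rec, m = p.get("tau_recdes", 75.0), p.get("m", 1.02)
        check_tau(tau_rec)
        if m <= 0:
            raise ValueError(f"m must be positive, got {m}")
        i_max = p.get("i_max", 30.0)
        tau_des = p.get("tau_des", 7.64)
        cond_ms, test_ms = p.get("cond_ms", 100.0), p.get("test_ms", 10.0)
        peak, t_pre = p.get("peak", 500.0), p.get("t_pre", 10.0)
        lit = np.asarray(hh_recovery_model(intervals, i_max, tau_rec, m), dtype=float)
        cond_norm = lit / i_max
        traces = []
        for k, (iv, frac) in enumerate(zip(intervals, cond_norm)):
            t2_on = t_pre + cond_ms + iv
            t = np.arange(0.0, t2_on + test_ms + 10.0 + 0.5 * dt, dt)
            y = np.zeros_like(t)
            p1 = (t >= t_pre) & (t <= t_pre + cond_ms)
            y[p1] = peak * np.exp(-(t[p1] - t_pre) / tau_des)
            p2 = (t >= t2_on) & (t <= t2_on + test_ms)
            y[p2] = frac * peak * np.exp(-(t[p2] - t2_on) / tau_des)
            y = -_noisy(y, noise_sd, peak, rng)
            traces.append(
                CurrentTrace(
                    t, y,
                    {"pulse1": (t_pre, t_pre + cond_ms), "pulse2": (t2_on, t2_on + test_ms)},
                    label=f"recovery_{k}",
                )
            )
        noisy_lit = _noisy(lit, noise_sd, float(lit.max()), rng)
        return TraceFixture(
            kind,
            {"tau_recdes": tau_rec, "m": m, "i_max": i_max, "intervals": intervals},
            traces,
            envelope_t=intervals,
            envelope_residual=noisy_lit if noise_sd else lit,
            envelope_conditioning=cond_norm,
        )

    if kind == "steady_state_pair":
        ratio = p.get("ratio", 0.032)
        tau = p.get("tau", 7.64)
        check_tau(tau)
        peak, t_app, t_pre = p.get("peak", 100.0), p.get("t_app", 1000.0), p.get("t_pre", 10.0)
        t = np.arange(0.0, t_pre + t_app + 0.5 * dt, dt)
        in_app = t >= t_pre
        ss = ratio * peak
        y_glu = np.zeros_like(t)
        y_glu[in_app] = ss + (peak - ss) * np.exp(-(t[in_app] - t_pre) / tau)
        y_ctz = np.zeros_like(t)
        y_ctz[in_app] = peak
        ann = {"application": (t_pre, t_pre + t_app)}
        glu = CurrentTrace(t, -_noisy(y_glu, noise_sd, peak, rng), ann, "glu")
        ctz = CurrentTrace(t, -_noisy(y_ctz, noise_sd, peak, rng), ann, "ctz")
        return TraceFixture(kind, {"ratio": ratio, "tau": tau, "peak": peak}, [glu, ctz])

    raise ValueError(f"unknown trace kind {kind!r}")
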