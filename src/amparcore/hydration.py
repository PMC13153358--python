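"""Water permeation and occupancy analysis of channel-gate trajectories.

The gate region is the slab between two planes set by the mean axial (z)
coordinate of the Cα tetrads of two gate residues (defaults: the M3
threonines labelled T617 and T625 in GluA2 numbering).  A permeation event
is a completed traversal: a water enters the slab through one boundary and
exits through the opposite one, any dwell length; re-exit through the
entry boundary cancels the pending event.  Both directions count.  Rates
are events per ns; the cumulative average at window k is the mean of the
per-window rates 1..k.

Waters are identified by their oxygen atom.  When a periodic box length
along the axis is supplied, coordinates are unwrapped first so wrap jumps
(> box/2 between frames) are never miscounted as crossings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .structures import StructureModel, SubunitMap, StructureError

__all__ = [
    "Trajectory",
    "GateSlab",
    "PermeationResult",
    "PermeationTracker",
    "build_gate_slab",
    "count_permeations",
    "cumulative_average",
    "water_occupancy",
    "water_z_coordinates",
]

_WATER_NAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O"}
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class Trajectory:
    """A multi-model coordinate set with a known frame spacing in ns."""

    stack: struc.AtomArrayStack
    dt_ns: float
    label: str = ""
    box_z: float | None = None

    def __post_init__(self) -> None:
        if self.dt_ns is None or self.dt_ns <= 0:
            raise ValueError("trajectory frame spacing dt_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.stack.stack_depth()

    @property
    def total_ns(self) -> float:
        return self.n_frames * self.dt_ns

    @classmethod
    def from_pdb(cls, path, dt_ns: float, label: str = "", box_z: float | None = None):
        from biotite.structure.io.pdb import PDBFile

        stack = PDBFile.read(str(path)).get_structure(model=None, altloc="first")
        return cls(stack, dt_ns, label or str(path), box_z)


@dataclass
class GateSlab:
    """Per-frame lower/upper gate-plane levels along the pore axis."""

    lower: np.ndarray   # (n_frames,)
    upper: np.ndarray   # (n_frames,)
    axis: str = "z"
    lower_label: str = "T617"
    upper_label: str = "T625"

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper level series must share a shape")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower gate plane must lie below upper in every frame")

    def for_frames(self, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
        if self.lower.size == 1:
            return (
                np.full(n_frames, self.lower[0]),
                np.full(n_frames, self.upper[0]),
            )
        if self.lower.size != n_frames:
            raise ValueError(
                f"slab defined for {self.lower.size} frames, trajectory has {n_frames}"
            )
        return self.lower, self.upper


def build_gate_slab(
    trajectory: Trajectory,
    smap: SubunitMap,
    lower_label: str = "T617",
    upper_label: str = "T625",
    axis: str = "z",
) -> GateSlab:
    """Gate planes from the mean axial Cα coordinate of two residue tetrads.

    If the labels arrive in the wrong vertical order the planes are swapped
    with a warning, so ``lower < upper`` always holds.
    """
    ax = _AXIS_INDEX[axis]
    stack = trajectory.stack

    def tetrad_level(label: str) -> np.ndarray:
        coords = []
        for pos in "ABCD":
            chain = smap.chain(pos)
            resid = smap.gate_residue(pos, label)
            mask = (
                (stack.chain_id == chain)
                & (stack.res_id == resid)
                & (stack.atom_name == "CA")
            )
            if mask.sum() != 1:
                raise StructureError(
                    f"gate residue {label} (chain {chain}, res {resid}): "
                    f"{mask.sum()} CA atoms in topology"
                )
            coords.append(stack.coord[:, mask, ax][:, 0])
        return np.mean(coords, axis=0)

    lo = tetrad_level(lower_label)
    hi = tetrad_level(upper_label)
    if np.mean(lo) > np.mean(hi):
        warnings.warn(
            f"gate labels given in reversed order ({lower_label} above "
            f"{upper_label}); swapping"
        )
        lo, hi = hi, lo
        lower_label, upper_label = upper_label, lower_label
    return GateSlab(lo, hi, axis, lower_label, upper_label)


def water_z_coordinates(
    trajectory: Trajectory, axis: str = "z"
) -> tuple[np.ndarray, np.ndarray]:
    """(water_ids, z) for water oxygens; z has shape (n_frames, n_waters)."""
    ax = _AXIS_INDEX[axis]
    stack = trajectory.stack
    mask = np.isin(stack.res_name, list(_WATER_NAMES)) & (
        np.char.startswith(stack.atom_name.astype(str), "O")
    )
    ids = stack.res_id[mask]
    z = stack.coord[:, mask, ax]
    return ids, z


def _unwrap(z: np.ndarray, box: float) -> np.ndarray:
    dz = np.diff(z, axis=0)
    shift = np.cumsum(-np.round(dz / box) * box, axis=0)
    out = z.copy()
    out[1:] += shift
    return out


@dataclass
class PermeationTracker:
    """Three-state (below | inside | above) per-water crossing tracker.

    Carries its state across chunks, so feeding a trajectory in contiguous
    pieces yields the same events as a single pass.
    """

    n_waters: int
    state: np.ndarray = field(init=False)        # -1 below, 0 inside, +1 above
    entry_side: np.ndarray = field(init=False)   # side through which a pending water entered
    events: list = field(default_factory=list)
    _frame: int = field(default=0, init=False)
    _entry_frame: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.state = np.zeros(self.n_waters, dtype=int)
        self.entry_side = np.zeros(self.n_waters, dtype=int)
        self._entry_frame = np.full(self.n_waters, -1, dtype=int)
        self._initialized = False

    @staticmethod
    def _classify(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
        s = np.zeros(z.shape, dtype=int)
        s[z < lo] = -1
        s[z > hi] = 1
        return s

    def update(self, z_frame: np.ndarray, lo: float, hi: float, ids=None) -> None:
        s = self._classify(np.asarray(z_frame, dtype=float), lo, hi)
        if not self._initialized:
            self.state = s
            # waters that start inside are treated as having no usable entry side
            self.entry_side = np.zeros(self.n_waters, dtype=int)
            self._initialized = True
            self._frame += 1
            return
        prev = self.state
        for w in np.flatnonzero(s != prev):
            a, b = prev[w], s[w]
            if a != 0 and b == 0:                      # outside -> inside
                self.entry_side[w] = a
                self._entry_frame[w] = self._frame
            elif a == 0 and b != 0:                    # inside -> outside
                if self.entry_side[w] != 0 and b == -self.entry_side[w]:
                    self._emit(w, b, ids)
                self.entry_side[w] = 0
                self._entry_frame[w] = -1
            elif a != 0 and b == -a:                   # jumped straight across
                self._entry_frame[w] = self._frame - 1
                self.entry_side[w] = a
                self._emit(w, b, ids)
                self.entry_side[w] = 0
                self._entry_frame[w] = -1
        self.state = s
        self._frame += 1

    def _emit(self, w: int, exit_side: int, ids) -> None:
        self.events.append(
            {
                "water_id": int(ids[w]) if ids is not None else int(w),
                "entry_frame": int(self._entry_frame[w]),
                "exit_frame": int(self._frame),
                "direction": "down" if exit_side == -1 else "up",
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["water_id", "entry_frame", "exit_frame", "direction"]
        )


@dataclass
class PermeationResult:
    events: pd.DataFrame
    rate: float                       # events / ns over the whole trajectory
    window_ns: float | None
    per_window_rates: np.ndarray | None
    cumulative_avg: np.ndarray | None
    occupancy: np.ndarray             # per-frame waters inside the slab
    total_ns: float

    @property
    def n_events(self) -> int:
        return len(self.events)


def count_permeations(
    trajectory: Trajectory | np.ndarray,
    slab: GateSlab,
    water_ids: np.ndarray | None = None,
    dt_ns: float | None = None,
    window_ns: float | None = None,
    box_z: float | None = None,
) -> PermeationResult:
    """Count completed water traversals of the gate slab.

    ``trajectory`` may be a :class:`Trajectory` (water oxygens are selected
    from it) or a raw ``(n_frames, n_waters)`` axial-coordinate array, in
    which case ``dt_ns`` is required.
    """
    if isinstance(trajectory, Trajectory):
        ids, z = water_z_coordinates(trajectory, slab.axis)
        dt_ns = trajectory.dt_ns
        box_z = box_z if box_z is not None else trajectory.box_z
    else:
        z = np.asarray(trajectory, dtype=float)
        ids = water_ids
        if dt_ns is None or dt_ns <= 0:
            raise ValueError("raw coordinate input requires a positive dt_ns")
    if z.ndim != 2:
        raise ValueError(f"expected (n_frames, n_waters) coordinates, got {z.shape}")
    n_frames, n_waters = z.shape
    if box_z is not None:
        z = _unwrap(z, box_z)
    lo, hi = slab.for_frames(n_frames)
    tracker = PermeationTracker(n_waters)
    for f in range(n_frames):
        tracker.update(z[f], lo[f], hi[f], ids)
    events = tracker.events_frame()
    total_ns = n_frames * dt_ns
    rate = len(events) / total_ns
    occupancy = np.sum((z >= lo[:, None]) & (z <= hi[:, None]), axis=1)
    per_window = cum = None
    if window_ns is not None:
        frames_per = max(int(round(window_ns / dt_ns)), 1)
        n_windows = int(np.ceil(n_frames / frames_per))
        counts = np.zeros(n_windows)
        if len(events):
            widx = np.minimum(events["exit_frame"] // frames_per, n_windows - 1)
            for w in widx:
                counts[w] += 1
        per_window = counts / (frames_per * dt_ns)
        cum = cumulative_average(per_window)
    return PermeationResult(
        events=events,
        rate=rate,
        window_ns=window_ns,
        per_window_rates=per_window,
        cumulative_avg=cum,
        occupancy=occupancy,
        total_ns=total_ns,
    )


def cumulative_average(rate_series) -> np.ndarray:
    """Element k is the mean of windows 1..k (running integral of the mean)."""
    r = np.asarray(rate_series, dtype=float)
    if r.size == 0:
        raise ValueError("cumulative average of an empty series")
    return np.cumsum(r) / np.arange(1, r.size + 1)


def water_occupancy(
    trajectory: Trajectory | np.ndarray,
    slab: GateSlab,
    per_level: dict[str, np.ndarray] | None = None,
    level_halfwidth: float = 2.0,
) -> pd.DataFrame:
    """Per-frame count of water oxygens inside the slab.

    ``per_level`` optionally maps residue labels to per-frame axial levels
    (e.g. from gate-residue tetrads); each named level adds a column
    counting waters within ± ``level_halfwidth`` Å of it.
    """
    if isinstance(trajectory, Trajectory):
        _, z = water_z_coordinates(trajectory, slab.axis)
    else:
        z = np.asarray(trajectory, dtype=float)
    n_frames = z.shape[0]
    lo, hi = slab.for_frames(n_frames)
    out = {"slab": np.sum((z >= lo[:, None]) & (z <= hi[:, None]), axis=1)}
    for label, level in (per_level or {}).items():
        lev = np.broadcast_to(np.atleast_1d(np.asarray(level, float)), (n_frames,))
        out[label] = np.sum(np.abs(z - lev[:, None]) <= level_halfwidth, axis=1)
    return pd.DataFrame(out)
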