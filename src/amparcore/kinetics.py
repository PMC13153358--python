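"""Receptor-kinetics descriptors from whole-cell current traces.

Four quantities characterize AMPA-receptor gating kinetics:

* τ_Des — time constant of desensitization, a single-exponential fit of the
  current decline during a prolonged (1 s) glutamate application;
* τ_Deact — time constant of deactivation, the same fit after a brief
  (2 ms) application;
* I_SS/I_max — steady-state over maximal current, the equilibrium fraction
  of non-desensitized receptors (the maximal current is measured with the
  desensitization blocker cyclothiazide, CTZ);
* τ_RecDes and m — recovery from desensitization, fitted to the
  Hodgkin–Huxley form  I(t) = (I_max^(1/m) − (I_max^(1/m) − 1)·e^(−t/τ))^m,
  where I is the peak current at interpulse interval t of a two-pulse
  protocol, I(0) = 1 and I(∞) = I_max.  m indexes the number of
  rate-determining transitions in the recovery pathway.

Sign convention: inward currents are negative; all peak/steady-state
detection operates on magnitude after baseline subtraction (baseline =
pre-application mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "CurrentTrace",
    "DecayFit",
    "RecoveryFit",
    "SteadyStateRatio",
    "KineticsError",
    "read_trace",
    "write_trace",
    "fit_exponential_decay",
    "hh_recovery_model",
    "build_recovery_envelope",
    "fit_recovery",
    "steady_state_ratio",
    "two_sample_ttest",
]


class KineticsError(RuntimeError):
    """Raised for unfittable traces or invalid kinetic parameters."""


@dataclass
class CurrentTrace:
    """A current-vs-time recording on a uniform millisecond grid.

    ``annotations`` holds stimulus windows as ``(t_on, t_off)`` tuples in
    ms, keyed e.g. ``application``, ``pulse1``, ``pulse2``.
    """

    time: np.ndarray     # ms
    current: np.ndarray  # pA (negative-going allowed)
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise ValueError("time and current must be equal-length 1-D arrays")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 0.01 * np.median(dt)):
            raise ValueError("time grid must be strictly increasing and uniform to 1%")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def baseline(self, window_key: str = "application") -> float:
        """Mean current before the first annotated stimulus (0 if none)."""
        t_on = min(w[0] for w in self.annotations.values()) if self.annotations else None
        if t_on is None:
            return 0.0
        pre = self.current[self.time < t_on]
        return float(pre.mean()) if pre.size else 0.0


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write as two-column delimited text with a YAML annotation sidecar."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([trace.time, trace.current]),
        header="time_ms\tcurrent_pA",
        delimiter="\t",
        comments="# ",
    )
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "label": trace.label,
                "annotations": {k: list(map(float, v)) for k, v in trace.annotations.items()},
            },
            fh,
        )
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t")
    annotations, label = {}, path.stem
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        annotations = {k: tuple(v) for k, v in (meta.get("annotations") or {}).items()}
        label = meta.get("label") or label
    return CurrentTrace(data[:, 0], data[:, 1], annotations, label)


def _signed_magnitude(trace: CurrentTrace) -> tuple[np.ndarray, float]:
    """Baseline-subtracted current flipped to positive-going.

    The flip uses the sign of the largest deflection rather than a
    pointwise absolute value: folding zero-mean tail noise into a
    positive floor would bias exponential fits toward shorter τ.
    """
    base = trace.baseline()
    dev = trace.current - base
    sign = np.sign(dev[np.argmax(np.abs(dev))]) or 1.0
    return dev * sign, base


# -- exponential decay -------------------------------------------------------


@dataclass(frozen=True)
class DecayFit:
    tau: float           # ms
    amplitude: float     # magnitude units of the trace
    baseline: float
    window: tuple[float, float]
    residual_norm: float
    converged: bool


def fit_exponential_decay(
    trace: CurrentTrace, window: str | tuple[float, float] = "auto"
) -> DecayFit:
    """Single-exponential fit A·exp(−t/τ) + C of a current decline.

    The automatic window runs from the peak (within the annotated
    application) to the end of the application.  The fit operates on the
    baseline-subtracted magnitude; a window that does not decay raises
    :class:`KineticsError` rather than returning a meaningless τ.
    """
    mag, base = _signed_magnitude(trace)
    if window == "auto":
        if "application" not in trace.annotations:
            raise KineticsError("auto window requires an 'application' annotation")
        t_on, t_off = trace.annotations["application"]
        in_app = (trace.time >= t_on) & (trace.time <= t_off)
        if not np.any(in_app):
            raise KineticsError("application window contains no samples")
        i_peak = np.flatnonzero(in_app)[np.argmax(mag[in_app])]
        window = (float(trace.time[i_peak]), float(t_off))
    t_lo, t_hi = window
    sel = (trace.time >= t_lo) & (trace.time <= t_hi)
    t = trace.time[sel] - t_lo
    y = mag[sel]
    if y.size < 10:
        raise KineticsError(f"decay window [{t_lo}, {t_hi}] has {y.size} < 10 samples")
    if y[0] <= y[-5:].mean() + 1e-12 * max(1.0, y[0]):
        raise KineticsError("window does not contain a decaying current")

    def model(t, A, tau, C):
        return A * np.exp(-t / tau) + C

    def jac(t, A, tau, C):
        e = np.exp(-t / tau)
        return np.column_stack([e, A * t * e / tau**2, np.ones_like(t)])

    A0 = y[0] - y[-1]
    C0 = y[-1]
    # crude log-linear tau guess over the upper part of the decay
    pos = y - C0 > 0.05 * max(A0, 1e-12)
    tau0 = max((t[pos][-1] - t[pos][0]) / 3.0, trace.dt) if pos.sum() > 2 else max(t[-1] / 3, trace.dt)
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[A0, tau0, C0], jac=jac, maxfev=10000,
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        raise KineticsError(f"exponential fit did not converge: {exc}") from exc
    A, tau, C = popt
    resid = float(np.linalg.norm(model(t, *popt) - y))
    return DecayFit(float(tau), float(A), base, (t_lo, t_hi), resid, True)


# -- Hodgkin–Huxley recovery -------------------------------------------------


def hh_recovery_model(
    t: np.ndarray | float, i_max: float, tau_recdes: float, m: float
) -> np.ndarray | float:
    """I(t) = (I_max^(1/m) − (I_max^(1/m) − 1)·exp(−t/τ_RecDes))^m.

    I(0) = 1 and I(t) → I_max as t → ∞; for m = 1 this is the plain
    single-exponential recovery I_max − (I_max − 1)·e^(−t/τ).
    """
    if tau_recdes <= 0 or m <= 0:
        raise KineticsError(f"tau_recdes and m must be positive, got {tau_recdes}, {m}")
    if i_max < 1:
        raise KineticsError(f"i_max must be >= 1 on this normalization, got {i_max}")
    root = i_max ** (1.0 / m)
    return (root - (root - 1.0) * np.exp(-np.asarray(t, dtype=float) / tau_recdes)) ** m


@dataclass(frozen=True)
class RecoveryFit:
    tau_recdes: float   # ms
    m: float
    i_max: float
    covariance: np.ndarray | None
    t: np.ndarray
    i: np.ndarray
    residual_norm: float
    normalized_to: str


def build_recovery_envelope(
    traces: Sequence[CurrentTrace], intervals: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Recovery envelope from two-pulse traces.

    Each trace must carry ``pulse1`` and ``pulse2`` annotations.  The point
    for a trace is the second-pulse peak magnitude normalized to its
    conditioning (first-pulse) peak; the interval is the pulse2 onset minus
    pulse1 offset unless ``intervals`` is given explicitly.
    """
    ts, points = [], []
    for k, trace in enumerate(traces):
        for key in ("pulse1", "pulse2"):
            if key not in trace.annotations:
                raise KineticsError(f"trace {trace.label!r} lacks annotation {key!r}")
        mag, _ = _signed_magnitude(trace)
        peaks = {}
        for key in ("pulse1", "pulse2"):
            t_on, t_off = trace.annotations[key]
            sel = (trace.time >= t_on) & (trace.time <= t_off)
            if not np.any(sel):
                raise KineticsError(f"trace {trace.label!r}: empty window {key!r}")
            peaks[key] = float(mag[sel].max())
        if peaks["pulse1"] <= 0:
            raise KineticsError(f"trace {trace.label!r}: zero conditioning peak")
        interval = (
            float(intervals[k])
            if intervals is not None
            else trace.annotations["pulse2"][0] - trace.annotations["pulse1"][1]
        )
        ts.append(interval)
        points.append(peaks["pulse2"] / peaks["pulse1"])
    order = np.argsort(ts)
    return np.asarray(ts)[order], np.asarray(points)[order]


_M_STARTS = (0.5, 1.0, 2.0, 4.0)


def fit_recovery(
    t: Sequence[float],
    i: Sequence[float],
    normalized_to: str = "residual",
) -> RecoveryFit:
    """Least-squares fit of the Hodgkin–Huxley recovery equation.

    ``normalized_to="residual"`` fits the printed equation literally, so the
    data are expected to start near 1 and rise to I_max (peaks normalized to
    the residual non-desensitized response).  ``normalized_to="conditioning"``
    fits I(t)/I_max, for envelopes normalized to the conditioning peak
    (starting near 1/I_max and saturating at 1).  A fixed multi-start grid
    over m keeps the optimization deterministic; the best residual wins.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    if t.shape != i.shape or t.ndim != 1:
        raise ValueError("t and i must be equal-length 1-D arrays")
    if t.size < 4:
        raise KineticsError(f"recovery fit needs >= 4 envelope points, got {t.size}")
    if normalized_to not in ("residual", "conditioning"):
        raise ValueError(f"unknown normalization {normalized_to!r}")

    def predict(params, tt):
        i_max, tau, m = params
        y = hh_recovery_model(tt, i_max, tau, m)
        return y / i_max if normalized_to == "conditioning" else y

    def resid(params):
        return predict(params, t) - i

    tau0 = float(np.median(t)) or 1.0
    if normalized_to == "residual":
        imax0 = max(float(i.max()), 1.0 + 1e-6)
    else:
        imax0 = max(1.0 / max(float(i.min()), 1e-3), 1.0 + 1e-6)
    best = None
    for m0 in _M_STARTS:
        try:
            sol = optimize.least_squares(
                resid,
                x0=[imax0, tau0, m0],
                bounds=([1.0 + 1e-12, 1e-9, 0.05], [1e6, 1e9, 50.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise KineticsError("recovery fit did not converge from any start")
    i_max, tau, m = best.x
    # Gauss-Newton covariance estimate from the final Jacobian
    try:
        jtj = best.jac.T @ best.jac
        dof = max(t.size - 3, 1)
        cov = np.linalg.inv(jtj) * 2 * best.cost / dof
    except np.linalg.LinAlgError:
        cov = None
    return RecoveryFit(
        tau_recdes=float(tau),
        m=float(m),
        i_max=float(i_max),
        covariance=cov,
        t=t,
        i=i,
        residual_norm=float(np.sqrt(2 * best.cost)),
        normalized_to=normalized_to,
    )


# -- steady-state fraction ---------------------------------------------------


@dataclass(frozen=True)
class SteadyStateRatio:
    i_ss: float
    i_max: float

    @property
    def ratio(self) -> float:
        return self.i_ss / self.i_max


def steady_state_ratio(
    trace_glu: CurrentTrace, trace_ctz: CurrentTrace
) -> SteadyStateRatio:
    """I_SS/I_max: steady-state fraction of non-desensitized receptors.

    I_SS is the mean magnitude over the final 10% of the glutamate
    application; I_max is the peak magnitude of the CTZ
    (desensitization-blocked) trace.
    """
    for tr, name in ((trace_glu, "trace_glu"), (trace_ctz, "trace_ctz")):
        if "application" not in tr.annotations:
            raise KineticsError(f"{name} lacks an 'application' annotation")
    t_on, t_off = trace_glu.annotations["application"]
    tail_start = t_off - 0.1 * (t_off - t_on)
    sel = (trace_glu.time >= tail_start) & (trace_glu.time <= t_off)
    if not np.any(sel):
        raise KineticsError("steady-state window contains no samples")
    mag_glu, _ = _signed_magnitude(trace_glu)
    i_ss = float(mag_glu[sel].mean())
    c_on, c_off = trace_ctz.annotations["application"]
    csel = (trace_ctz.time >= c_on) & (trace_ctz.time <= c_off)
    mag_ctz, _ = _signed_magnitude(trace_ctz)
    i_max = float(mag_ctz[csel].max())
    if i_max <= 0:
        raise KineticsError("CTZ trace has zero maximal current")
    return SteadyStateRatio(i_ss=i_ss, i_max=i_max)


def two_sample_ttest(x: Sequence[float], y: Sequence[float]):
    """Two-sided two-sample t-test (convenience wrapper)."""
    return stats.ttest_ind(np.asarray(x, float), np.asarray(y, float))
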