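"""Numerical integration of the impulsive delay system.

Fixed-step classic Runge-Kutta on each inter-impulse segment, with the grid
snapped to every impulse time.  Delayed state lookups use cubic Hermite
interpolation of the stored solution; lookups never interpolate across a jump
(the node list duplicates each impulse time with pre- and post-jump values).

Delays smaller than the step are handled by iterating each step to a fixed
point: the first pass uses first-order extrapolation for lookups inside the
step being computed, later passes interpolate the provisional Hermite segment.
Three passes restore the fourth-order behaviour of the base scheme.

The state can be advanced either in linear space (x itself) or in log space
(z = ln x, which guarantees positivity); nodes are always stored in linear
space so that delayed lookups and exported trajectories are in x.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .model import ImpulseSchedule, SchoenerModel

__all__ = [
    "InitialHistory",
    "Jump",
    "Trajectory",
    "IntegrationError",
    "integrate_schoener",
    "integrate_logistic",
    "history_eval",
    "trajectory_to_csv",
    "trajectory_from_csv",
]


class IntegrationError(RuntimeError):
    pass


class InitialHistory:
    """Per-species state on an interval ``[t0 - span, t0]``.

    Either constant per species or tabulated (linear interpolation).  The
    value at ``t0`` is the starting state and must be strictly positive.
    """

    def __init__(self, fn, span: float, value0: np.ndarray, kind: str = "custom"):
        self._fn = fn
        self.span = float(span)
        self.value0 = np.asarray(value0, dtype=float)
        self.kind = kind
        if np.any(self.value0 <= 0.0):
            raise IntegrationError("initial state (history at 0) must be strictly positive")

    @classmethod
    def constant(cls, values, span: float = math.inf) -> "InitialHistory":
        vals = np.atleast_1d(np.asarray(values, dtype=float))
        if np.any(vals < 0.0):
            raise IntegrationError("history values must be nonnegative")
        return cls(lambda s: vals, span, vals, kind="constant")

    @classmethod
    def from_table(cls, offsets, values) -> "InitialHistory":
        """Tabulated history; ``offsets`` in [-span, 0], ``values`` shape (n, d)."""
        offsets = np.asarray(offsets, dtype=float)
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if offsets[0] > -0.0 or offsets[-1] != 0.0:
            raise IntegrationError("history table must end at offset 0")
        if np.any(values < 0.0):
            raise IntegrationError("history values must be nonnegative")

        def fn(s):
            return np.array(
                [np.interp(s, offsets, values[:, j]) for j in range(values.shape[1])]
            )

        return cls(fn, -float(offsets[0]), values[-1], kind="table")

    def __call__(self, s: float) -> np.ndarray:
        """Evaluate at offset ``s <= 0`` relative to the start time."""
        return self._fn(s)

    @property
    def n_species(self) -> int:
        return self.value0.size


@dataclass(frozen=True)
class Jump:
    time: float
    pre: np.ndarray
    post: np.ndarray


@dataclass
class Trajectory:
    """Piecewise-smooth solution with explicit jump records.

    ``states[i]`` holds the pre-jump value whenever ``times[i]`` is an impulse
    time (left-continuity convention); the corresponding post-jump value is in
    ``jumps``.  Internal node arrays duplicate each jump time to support
    interpolation that never straddles a jump.
    """

    times: np.ndarray
    states: np.ndarray
    jumps: list
    step: float
    species_count: int
    t0: float = 0.0
    _node_t: np.ndarray = field(default=None, repr=False)
    _node_x: np.ndarray = field(default=None, repr=False)
    _node_dx: np.ndarray = field(default=None, repr=False)
    _history: InitialHistory | None = field(default=None, repr=False)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def jump_times(self) -> np.ndarray:
        return np.array([j.time for j in self.jumps])

    def is_jump_row(self) -> np.ndarray:
        jt = self.jump_times
        if jt.size == 0:
            return np.zeros(self.times.size, dtype=bool)
        return np.isin(self.times, jt)

    def eval(self, t: float, side: str = "left") -> np.ndarray:
        """Interpolated state at ``t`` (``side`` selects pre/post at a jump)."""
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        nt, nx, ndx = self._node_t, self._node_x, self._node_dx
        if t < self.t0:
            if self._history is None:
                raise IntegrationError(f"t={t} precedes the trajectory and no history is attached")
            if t < self.t0 - self._history.span - 1e-9:
                raise IntegrationError(f"t={t} precedes the initial history start")
            return np.array(self._history(t - self.t0), dtype=float)
        if t > nt[-1] + 1e-12:
            raise IntegrationError(f"t={t} beyond trajectory end {nt[-1]}")
        lo = int(np.searchsorted(nt, t, side="left"))
        hi = int(np.searchsorted(nt, t, side="right"))
        if lo < hi:  # exact node hit (possibly duplicated at a jump)
            return nx[lo].copy() if side == "left" else nx[hi - 1].copy()
        i = min(lo, nt.size - 1)
        ta, tb = nt[i - 1], nt[i]
        return _hermite(t, ta, tb, nx[i - 1], nx[i], ndx[i - 1], ndx[i])

    def to_csv(self, csv_path, json_path=None) -> None:
        trajectory_to_csv(self, csv_path, json_path)


def _hermite(u, ta, tb, xa, xb, da, db):
    h = tb - ta
    s = (u - ta) / h
    h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
    h10 = s * (1.0 - s) ** 2
    h01 = s * s * (3.0 - 2.0 * s)
    h11 = s * s * (s - 1.0)
    return h00 * xa + h10 * h * da + h01 * xb + h11 * h * db


class _Engine:
    """Segment-wise RK4 driver with delayed lookups and jump handling."""

    def __init__(self, F, d, t0, t1, step, points, factors, history, space):
        if step <= 0:
            raise IntegrationError("step must be positive")
        if space not in ("linear", "log"):
            raise IntegrationError("space must be 'linear' or 'log'")
        self.F = F
        self.d = d
        self.t0, self.t1 = float(t0), float(t1)
        self.step = float(step)
        self.space = space
        self.history = history
        # impulse points strictly inside (t0, t1]; a point exactly at t0 is
        # part of the past (the history value at 0 is already post-jump)
        mask = (points > t0 + 1e-12) & (points <= t1 + 1e-12)
        self.points = points[mask]
        self.factors = factors[mask] if factors.size else factors.reshape(0, d)
        n_sub_total = 0
        bounds = np.concatenate(([t0], self.points[self.points < t1 - 1e-12], [t1]))
        self.bounds = bounds
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_sub_total += max(1, math.ceil((b - a) / step - 1e-9))
        cap = n_sub_total + 2 * len(bounds) + 8
        self.node_t = np.empty(cap)
        self.node_x = np.empty((cap, d))
        self.node_dx = np.empty((cap, d))
        self.post_dup = np.zeros(cap, dtype=bool)
        self.n = 0
        self.jumps: list[Jump] = []

    # -- state-space conversions -------------------------------------------
    def to_x(self, y):
        return np.exp(y) if self.space == "log" else y

    def to_y(self, x):
        return np.log(x) if self.space == "log" else x

    def dx_from(self, y, dy):
        return np.exp(y) * dy if self.space == "log" else dy

    # -- node bookkeeping ---------------------------------------------------
    def append(self, t, y, dy, post_dup=False):
        i = self.n
        self.node_t[i] = t
        self.node_x[i] = self.to_x(y)
        self.node_dx[i] = self.dx_from(y, dy)
        self.post_dup[i] = post_dup
        self.n += 1
        return i

    def overwrite(self, i, t, y, dy):
        self.node_t[i] = t
        self.node_x[i] = self.to_x(y)
        self.node_dx[i] = self.dx_from(y, dy)

    # -- delayed lookup -----------------------------------------------------
    def lookup_x(self, u, j):
        nt = self.node_t
        n = self.n
        if u <= self.t0:
            if u >= self.t0 - 1e-14:
                return self.node_x[0, j]
            if self.history is None or u < self.t0 - self.history.span - 1e-9:
                raise IntegrationError(
                    f"delayed lookup at t={u} precedes the initial history start"
                )
            return float(self.history(u - self.t0)[j])
        if u >= nt[n - 1]:
            if u == nt[n - 1]:
                return float(self.node_x[n - 1, j])
            i = n - 1  # first-order continuation; refined by correction passes
            return self.node_x[i, j] + self.node_dx[i, j] * (u - nt[i])
        if n >= 2 and nt[n - 2] < u:  # fast path: small delays land in the last interval
            i = n - 1
        else:
            lo = int(np.searchsorted(nt[:n], u, side="left"))
            hi = int(np.searchsorted(nt[:n], u, side="right"))
            if lo < hi:
                return self.node_x[lo, j]  # pre-jump value at an exact hit
            i = lo
        ta, tb = nt[i - 1], nt[i]
        return float(
            _hermite(u, ta, tb, self.node_x[i - 1, j], self.node_x[i, j],
                     self.node_dx[i - 1, j], self.node_dx[i, j])
        )

    def rhs(self, t, y):
        x_stage = self.to_x(y)

        def lag(j, tau):
            if tau <= 0.0:
                return x_stage[j] if self.d > 1 else float(x_stage[j])
            return self.lookup_x(t - tau, j)

        Fv = self.F(t, lag)
        if self.space == "log":
            return Fv
        return x_stage * Fv

    def rk4(self, t, y, h):
        k1 = self.rhs(t, y)
        k2 = self.rhs(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = self.rhs(t + 0.5 * h, y + 0.5 * h * k2)
        k4 = self.rhs(t + h, y + h * k3)
        return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    def run(self, y0, min_pos_delay):
        y = np.asarray(y0, dtype=float).copy()
        dy0 = self.rhs(self.t0, y)
        self.append(self.t0, y, dy0)
        bounds = self.bounds
        pt_idx = 0
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_sub = max(1, math.ceil((b - a) / self.step - 1e-9))
            h = (b - a) / n_sub
            passes = 3 if (min_pos_delay is not None and 0.0 < min_pos_delay < h) else 1
            for i in range(n_sub):
                t_n = a + i * h
                t_new = b if i == n_sub - 1 else a + (i + 1) * h
                node_i = None
                for _ in range(passes):
                    y_new = self.rk4(t_n, y, t_new - t_n)
                    dy_new = self.rhs(t_new, y_new)
                    if node_i is None:
                        node_i = self.append(t_new, y_new, dy_new)
                    else:
                        self.overwrite(node_i, t_new, y_new, dy_new)
                y = y_new
                if self.space == "linear" and np.any(self.to_x(y) <= 0.0):
                    raise IntegrationError(
                        f"state became nonpositive at t={t_new}; reduce the step "
                        "or integrate in log space"
                    )
            # apply the impulse if this boundary is an impulse point
            if pt_idx < self.points.size and abs(self.points[pt_idx] - b) <= 1e-9:
                fac = self.factors[pt_idx]
                pre = self.to_x(y).copy()
                post = fac * pre
                self.jumps.append(Jump(time=float(b), pre=pre, post=post))
                y = self.to_y(post)
                dy_post = self.rhs(b, y)
                self.append(b, y, dy_post, post_dup=True)
                pt_idx += 1
        return self.build(min_pos_delay)

    def build(self, min_pos_delay) -> Trajectory:
        n = self.n
        keep = ~self.post_dup[:n]
        traj = Trajectory(
            times=self.node_t[:n][keep].copy(),
            states=self.node_x[:n][keep].copy(),
            jumps=self.jumps,
            step=self.step,
            species_count=self.d,
            t0=self.t0,
            _node_t=self.node_t[:n].copy(),
            _node_x=self.node_x[:n].copy(),
            _node_dx=self.node_dx[:n].copy(),
            _history=self.history,
        )
        return traj


def _schedule_factors(schedule: ImpulseSchedule, d: int):
    if schedule is None or schedule.is_empty:
        return np.empty(0), np.empty((0, d))
    pts = schedule.points
    coeffs = schedule.coefficients
    if coeffs.shape[1] != d:
        raise IntegrationError(
            f"schedule carries {coeffs.shape[1]} species, model has {d}"
        )
    return pts, 1.0 + coeffs


def default_step(schedule: ImpulseSchedule | None) -> float:
    gap = schedule.theta() if schedule is not None and not schedule.is_empty else math.inf
    if math.isinf(gap):
        return 0.01
    return min(0.01, gap / 100.0)


def integrate_schoener(
    model: SchoenerModel,
    history: InitialHistory,
    horizon: tuple[float, float],
    step: float | None = None,
    space: str = "log",
) -> Trajectory:
    """Integrate the two-species impulsive delay system over ``horizon``."""
    if history.n_species != 2:
        raise IntegrationError("model requires a two-species history")
    t0, t1 = float(horizon[0]), float(horizon[1])
    if step is None:
        step = default_step(model.schedule)
    delays = model.delays
    if history.span < model.tau_max / 2.0 - 1e-12:
        # the history must cover the largest single delay (tau_max is twice it)
        raise IntegrationError(
            f"history span {history.span} does not cover the largest delay"
        )
    a10, a20 = model.a10, model.a20
    a11, a12, a21, a22 = model.a11, model.a12, model.a21, model.a22
    m1, m2, c1, c2 = model.m1, model.m2, model.c1, model.c2
    t10, t11, t12 = delays["tau10"], delays["tau11"], delays["tau12"]
    t20, t21, t22 = delays["tau20"], delays["tau21"], delays["tau22"]

    coef_cache: dict[float, tuple] = {}

    def coefs_at(t):
        # stage times repeat across correction passes; memoize per time
        vals = coef_cache.get(t)
        if vals is None:
            vals = (a10(t), a20(t), a11(t), a12(t), a21(t), a22(t), m1(t), m2(t), c1(t), c2(t))
            if len(coef_cache) > 64:
                coef_cache.clear()
            coef_cache[t] = vals
        return vals

    def F(t, lag):
        v10, v20, v11, v12, v21, v22, vm1, vm2, vc1, vc2 = coefs_at(t)
        f1 = v10 / (lag(0, t10) + vm1) - v11 * lag(0, t11) - v12 * lag(1, t12) - vc1
        f2 = v20 / (lag(1, t20) + vm2) - v21 * lag(0, t21) - v22 * lag(1, t22) - vc2
        return np.array([f1, f2])

    pts, factors = _schedule_factors(model.schedule, 2)
    engine = _Engine(F, 2, t0, t1, step, pts, factors, history, space)
    pos = [tau for tau in delays.values() if tau > 0]
    y0 = engine.to_y(history.value0)
    return engine.run(y0, min(pos) if pos else None)


def integrate_logistic(
    a: float,
    b: float,
    schedule: ImpulseSchedule | None = None,
    delay: float = 0.0,
    x0: float = 1.0,
    horizon: tuple[float, float] = (0.0, 100.0),
    step: float = 0.01,
    space: str = "linear",
    history: InitialHistory | None = None,
) -> Trajectory:
    """Scalar trajectory of ``x' = x*(a - b*x(t - delay))`` with jumps ``(1+h_k)``.

    ``delay = 0`` recovers the plain impulsive logistic equation.  ``b`` may be
    zero (pure exponential growth/decay with jumps); ``a`` may have any sign —
    positivity requirements belong to the bound computations, not the solver.
    """
    if b < 0:
        raise IntegrationError("density dependence b must be nonnegative")
    if delay < 0:
        raise IntegrationError("delay must be nonnegative")
    t0, t1 = float(horizon[0]), float(horizon[1])
    if history is None:
        history = InitialHistory.constant([x0])
    if history.n_species != 1:
        raise IntegrationError("logistic history must be scalar")

    def F(t, lag):
        return np.array([a - b * lag(0, delay)])

    if schedule is None:
        schedule = ImpulseSchedule.empty((t0, t1))
    pts, factors = _schedule_factors(schedule, 1)
    engine = _Engine(F, 1, t0, t1, step, pts, factors, history, space)
    y0 = engine.to_y(history.value0)
    return engine.run(y0, delay if delay > 0 else None)


def history_eval(traj: Trajectory, t: float, side: str = "left") -> np.ndarray:
    """State at ``t`` (including the initial history range); see :meth:`Trajectory.eval`."""
    return traj.eval(t, side=side)


# ---------------------------------------------------------------------------
# round-trippable text export
# ---------------------------------------------------------------------------

def trajectory_to_csv(traj: Trajectory, csv_path, json_path=None) -> None:
    """Write ``t, x1..xd, is_jump`` rows plus a JSON sidecar of jump records."""
    is_jump = traj.is_jump_row()
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t"] + [f"x{j + 1}" for j in range(traj.species_count)] + ["is_jump"])
        for i, t in enumerate(traj.times):
            row = [f"{t:.17g}"] + [f"{v:.17g}" for v in traj.states[i]] + [int(is_jump[i])]
            w.writerow(row)
    if json_path is not None:
        payload = {
            "step": traj.step,
            "t0": traj.t0,
            "species_count": traj.species_count,
            "jumps": [
                {"time": j.time, "pre": list(map(float, j.pre)), "post": list(map(float, j.post))}
                for j in traj.jumps
            ],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def trajectory_from_csv(csv_path, json_path=None) -> Trajectory:
    """Reconstruct a trajectory from its CSV (+ optional JSON sidecar).

    Values round-trip bit-exactly; interpolation on a loaded trajectory uses
    finite-difference derivative estimates and is therefore approximate.
    """
    data = np.genfromtxt(csv_path, delimiter=",", names=True)
    times = np.atleast_1d(data["t"])
    d = len(data.dtype.names) - 2
    states = np.column_stack([np.atleast_1d(data[f"x{j + 1}"]) for j in range(d)])
    jumps: list[Jump] = []
    step = float(np.min(np.diff(times))) if times.size > 1 else 0.0
    t0 = float(times[0])
    if json_path is not None:
        with open(json_path) as fh:
            payload = json.load(fh)
        step = float(payload.get("step", step))
        t0 = float(payload.get("t0", t0))
        jumps = [
            Jump(time=float(j["time"]), pre=np.array(j["pre"]), post=np.array(j["post"]))
            for j in payload["jumps"]
        ]
    node_t, node_x = [], []
    jt = {j.time: j for j in jumps}
    for i, t in enumerate(times):
        node_t.append(t)
        node_x.append(states[i])
        if t in jt and i + 1 < times.size:
            node_t.append(t)
            node_x.append(jt[t].post)
    node_t = np.asarray(node_t)
    node_x = np.asarray(node_x)
    node_dx = np.gradient(node_x, axis=0, edge_order=1) / max(step, 1e-12)
    return Trajectory(
        times=times,
        states=states,
        jumps=jumps,
        step=step,
        species_count=d,
        t0=t0,
        _node_t=node_t,
        _node_x=node_x,
        _node_dx=node_dx,
        _history=None,
    )
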