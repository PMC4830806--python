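"""Trajectory-level verification of the certificates.

Empirical tail extrema stand in for lim inf / lim sup, invariant-set
membership is checked on every stored (pre- and post-jump) state, and the
stability certificate is probed two ways: trajectory-pair convergence and
numerical evaluation of the certifying functional ``V``.

``V`` is built from log-state differences ``|z_i - z_i*|`` (``z = ln x``):
a weighted pointwise term plus single and double delay-window integrals.
Because both trajectories share the same multiplicative jumps, ``z``
differences are continuous across impulses and ``V`` is analytically
unchanged by a jump — the numerical check below confirms this to quadrature
precision.  The double integrals are reduced to single weighted integrals
over the outer window (integrating out the inner variable over its
triangular region) before quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .integrator import IntegrationError, Trajectory
from .model import SchoenerModel
from .theory import PermanenceBounds

__all__ = [
    "LyapunovEvaluation",
    "tail_extrema",
    "invariant_set_check",
    "pair_distance",
    "lyapunov_V",
    "lyapunov_checks",
]


@dataclass(frozen=True)
class LyapunovEvaluation:
    V: float
    V1: float
    V2: float
    V3: float
    V4: float
    lambda1: float
    lambda2: float
    t: float


def tail_extrema(traj: Trajectory, fraction: float = 0.25):
    """Per-species (min, max) over the final ``fraction`` of the horizon.

    Post-jump values of impulses inside the window are included.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    t_lo = traj.t_end - fraction * (traj.t_end - traj.t0)
    mask = traj.times >= t_lo - 1e-12
    if not mask.any():
        raise ValueError("empty tail window")
    vals = [traj.states[mask]]
    for j in traj.jumps:
        if j.time >= t_lo - 1e-12:
            vals.append(j.post[None, :])
    stacked = np.vstack(vals)
    return stacked.min(axis=0), stacked.max(axis=0)


def invariant_set_check(
    traj: Trajectory,
    bounds: PermanenceBounds,
    tol: float = 1e-6,
) -> bool:
    """True iff the trajectory never leaves ``{N_i <= x_i <= M_i}``.

    Precondition: the initial history itself lies in the set — otherwise the
    question is ill-posed and the call refuses.
    """
    lo = np.array([bounds.N1, bounds.N2])
    hi = np.array([bounds.M1, bounds.M2])
    hist = traj._history
    if hist is not None:
        span = hist.span if math.isfinite(hist.span) else 1.0
        for s in np.linspace(-span, 0.0, 21):
            v = np.asarray(hist(s), dtype=float)
            if np.any(v < lo - tol) or np.any(v > hi + tol):
                raise ValueError(
                    f"initial history leaves the candidate invariant set at offset {s}"
                )
    vals = [traj.states]
    for j in traj.jumps:
        vals.append(j.post[None, :])
    stacked = np.vstack(vals)
    return bool(np.all(stacked >= lo - tol) and np.all(stacked <= hi + tol))


def pair_distance(trajA: Trajectory, trajB: Trajectory, norm: str = "sup") -> float:
    """Distance between two trajectories on a shared grid.

    ``sup``: maximum over the final quarter of the horizon of the summed
    per-species absolute difference; ``terminal``: that sum at the last point.
    """
    if trajA.times.shape != trajB.times.shape or not np.array_equal(trajA.times, trajB.times):
        raise IntegrationError("pair_distance requires identical time grids")
    diff = np.abs(trajA.states - trajB.states).sum(axis=1)
    if norm == "terminal":
        return float(diff[-1])
    if norm == "sup":
        t_lo = trajA.t_end - 0.25 * (trajA.t_end - trajA.t0)
        return float(diff[trajA.times >= t_lo - 1e-12].max())
    raise ValueError("norm must be 'sup' or 'terminal'")


def _z_diff(trajA: Trajectory, trajB: Trajectory, t: float, side: str = "left") -> np.ndarray:
    xa = trajA.eval(t, side=side)
    xb = trajB.eval(t, side=side)
    return np.abs(np.log(xa) - np.log(xb))


def _window_integral(trajA, trajB, species, t, T1, T2, n_nodes=17) -> float:
    """Reduced double integral: ``int_{t-T2}^{t} w(r) |dz(r)| dr`` with
    weight ``w(r) = min(T2 - T1, r - t + T2)`` (0 <= T1 <= T2)."""
    if T2 <= 0 or T2 <= T1:
        return 0.0

    def g(r):
        return _z_diff(trajA, trajB, r)[species]

    total = 0.0
    # ramp part on [t-T2, t-T1], weight r - (t - T2)
    rs = np.linspace(t - T2, t - T1, n_nodes)
    gs = np.array([g(r) for r in rs])
    total += np.trapezoid(gs * (rs - (t - T2)), rs)
    # flat part on [t-T1, t], weight T2 - T1
    if T1 > 0:
        rs = np.linspace(t - T1, t, n_nodes)
        gs = np.array([g(r) for r in rs])
        total += (T2 - T1) * np.trapezoid(gs, rs)
    return float(total)


def _plain_integral(trajA, trajB, species, t, T, n_nodes=17) -> float:
    if T <= 0:
        return 0.0
    rs = np.linspace(t - T, t, n_nodes)
    gs = np.array([_z_diff(trajA, trajB, r)[species] for r in rs])
    return float(np.trapezoid(gs, rs))


def lyapunov_V(
    trajA: Trajectory,
    trajB: Trajectory,
    model: SchoenerModel,
    bounds: PermanenceBounds,
    lambda1: float,
    lambda2: float,
    t: float,
    side: str = "left",
) -> LyapunovEvaluation:
    """Evaluate the certifying functional ``V = V1 + V2 + V3 + V4`` at ``t``.

    ``V1`` weights the pointwise log-state differences; ``V2`` (first species
    memory), ``V3`` (second species memory) and ``V4`` (cross-coupling tails)
    integrate ``|z_i - z_i*|`` over delay windows with the certified constant
    prefactors.  ``side`` selects the pre/post value of the pointwise term at
    an impulse time.
    """
    M1, M2, N1, N2 = bounds.M1, bounds.M2, bounds.N1, bounds.N2
    d = model.delay
    a10u, a20u = model.a10.sup, model.a20.sup
    a11u, a22u = model.a11.sup, model.a22.sup
    a12u, a21u = model.a12.sup, model.a21.sup
    m1l, m2l = model.m1.inf, model.m2.inf
    q1 = (N1 + m1l) ** 2
    q2 = (N2 + m2l) ** 2

    dz = _z_diff(trajA, trajB, t, side=side)
    V1 = lambda1 * dz[0] + lambda2 * dz[1]

    # (coef, species index, inner delay T1, outer reach T2)
    v2_terms = [
        (lambda1 * (a10u * M1 / q1) ** 2, 0, d(1, 0), 2 * d(1, 0)),
        (lambda1 * a10u * a11u * M1**2 / q1, 0, d(1, 1), d(1, 1) + d(1, 0)),
        (lambda1 * a10u * a11u * M1**2 / q1, 0, d(1, 0), d(1, 0) + d(1, 1)),
        (lambda1 * a11u**2 * M1**2, 0, d(1, 1), 2 * d(1, 1)),
        (lambda2 * a20u * a21u * M1 * M2 / q2, 0, d(2, 1), d(2, 1) + d(2, 0)),
        (lambda2 * a21u * a22u * M1 * M2, 0, d(2, 1), d(2, 1) + d(2, 2)),
    ]
    v3_terms = [
        (lambda1 * a10u * a12u * M1 * M2 / q1, 1, d(1, 2), d(1, 2) + d(1, 0)),
        (lambda1 * a11u * a12u * M1 * M2, 1, d(1, 2), d(1, 2) + d(1, 1)),
        (lambda2 * (a20u * M2 / q2) ** 2, 1, d(2, 0), 2 * d(2, 0)),
        (lambda2 * a20u * a22u * M2**2 / q2, 1, d(2, 2), d(2, 2) + d(2, 0)),
        (lambda2 * a20u * a22u * M2**2 / q2, 1, d(2, 0), d(2, 0) + d(2, 2)),
        (lambda2 * a22u**2 * M2**2, 1, d(2, 2), 2 * d(2, 2)),
    ]
    V2 = sum(c * _window_integral(trajA, trajB, sp, t, T1, T2) for c, sp, T1, T2 in v2_terms)
    V3 = sum(c * _window_integral(trajA, trajB, sp, t, T1, T2) for c, sp, T1, T2 in v3_terms)
    V4 = lambda2 * a21u * M1 * _plain_integral(trajA, trajB, 0, t, d(2, 1)) + (
        lambda1 * a12u * M2 * _plain_integral(trajA, trajB, 1, t, d(1, 2))
    )
    return LyapunovEvaluation(
        V=float(V1 + V2 + V3 + V4),
        V1=float(V1), V2=float(V2), V3=float(V3), V4=float(V4),
        lambda1=lambda1, lambda2=lambda2, t=t,
    )


def lyapunov_checks(
    trajA: Trajectory,
    trajB: Trajectory,
    model: SchoenerModel,
    bounds: PermanenceBounds,
    lambdas: tuple[float, float],
    checkpoints,
) -> dict:
    """Verify jump invariance and checkpoint monotonicity of ``V``.

    Returns a report with the maximal relative jump violation, the checkpoint
    values, and the maximal increase between successive checkpoints (a
    negative or zero value means ``V`` was non-increasing).  Monotonicity is
    reported, not asserted: without a valid stability certificate no claim is
    made.
    """
    lam1, lam2 = lambdas
    pairs = []
    for j in trajA.jumps:
        if not (trajA.t0 < j.time <= trajA.t_end):
            continue
        v_pre = lyapunov_V(trajA, trajB, model, bounds, lam1, lam2, j.time, side="left")
        v_post = lyapunov_V(trajA, trajB, model, bounds, lam1, lam2, j.time, side="right")
        pairs.append((v_pre.V, v_post.V))
    # V decays by orders of magnitude along the run; measure jump defects
    # against the functional's scale, not against a vanishing local value
    scale = max((p for p, _ in pairs), default=0.0)
    abs_viol = max((abs(q - p) for p, q in pairs), default=0.0)
    jump_viol = abs_viol / scale if scale > 0 else 0.0
    values = [
        lyapunov_V(trajA, trajB, model, bounds, lam1, lam2, float(t)).V for t in checkpoints
    ]
    increases = [b - a for a, b in zip(values[:-1], values[1:])]
    max_increase = max(increases) if increases else 0.0
    return {
        "jump_max_violation": jump_viol,
        "jump_max_abs_violation": abs_viol,
        "jump_scale": scale,
        "checkpoints": [float(t) for t in checkpoints],
        "V_values": values,
        "nonincreasing": max_increase <= 0.0,
        "max_increase": max_increase,
    }
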