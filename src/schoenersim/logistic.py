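"""Scalar impulsive logistic theory: transition factor, recurrent orbit, bounds.

For ``x' = x*(a - b*x)`` with multiplicative jumps ``(1+h_k)`` at times
``tau_k``, the reciprocal substitution ``u = 1/x`` linearizes the equation;
its transition (Cauchy) factor is an exponential decay times the product of
``1/(1+h_j)`` over the jumps crossed.  The unique globally stable positive
recurrent orbit is ``x*(t) = [b * int_{-inf}^t W(t,s) ds]^{-1}``, which this
module evaluates in closed form segment by segment (the integrand is a pure
exponential between jumps, so no numerical quadrature is needed).

The delayed variants carry bound constants:

* upper: ``limsup x <= M = a / (eta * B * (1 - e^{-a*theta}))`` with
  ``B = inf_t b * prod_{tau_k in [t-tau, t)} (1+h_k)^{-1} * e^{-a*tau}``,
* lower: ``liminf x >= N = (a - xi+*A) / (e^{xi+*A} * D)`` with
  ``D = sup_t b * prod_{tau_k in [t-tau, t)} (1+h_k)^{-1} * e^{-(a-b*M)*tau}``,

where ``theta`` is the minimal gap, ``eta`` the worst two-consecutive-jump
product (capped at 1), ``xi = ln sup_k 1/(1+h_k)`` and ``A`` the window
counting constant.  All window extrema are exact: the products are piecewise
constant in ``t`` with breakpoints at ``tau_k`` and ``tau_k + tau``.

Sign caveat: the jump-counting exponent ``xi`` enters the lower bound only
through its nonnegative part ``xi+ = max(xi, 0)``.  The counting inequality
``i(s,t) <= A(t-s) + A`` turns ``e^{i*xi}`` into ``e^{(A(t-s)+A)*xi}`` only
when ``xi >= 0``; for nonnegative jump coefficients ``xi <= 0`` and the valid
bound is ``e^{i*xi} <= 1``.  Using the raw (negative) ``xi`` would inflate
the lower bound beyond the true infimum — directly observable against the
closed-form orbit.  ``ScalarBoundSet`` stores the raw ``xi`` and ``alpha``
alongside the clamped bound.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .model import ImpulseSchedule, ModelError, schedule_A, _h_extrema_products

__all__ = [
    "ImpulsiveLogisticParams",
    "ScalarBoundSet",
    "cauchy_W",
    "logistic_ap_solution",
    "logistic_scalar_bounds",
    "window_product_extrema",
]


@dataclass(frozen=True)
class ImpulsiveLogisticParams:
    a: float
    b: float
    schedule: ImpulseSchedule
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ModelError("logistic theory requires a > 0 and b > 0")
        if self.delay < 0:
            raise ModelError("delay must be nonnegative")
        if not self.schedule.is_empty and self.schedule.n_species != 1:
            raise ModelError("scalar theory needs a single-species schedule")


@dataclass(frozen=True)
class ScalarBoundSet:
    xi: float
    alpha: float
    theta: float
    eta: float
    A: int
    B: float
    D: float
    M: float
    N: float

    @property
    def xi_plus(self) -> float:
        """Nonnegative part of ``xi``, the exponent actually valid in lower bounds."""
        return max(self.xi, 0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    def orbit_bracket(self, a: float, b: float) -> tuple[float, float]:
        """Valid enclosure of the recurrent orbit of the undelayed equation."""
        lo = (a - self.xi_plus * self.A) / (math.exp(self.xi_plus * self.A) * b)
        decay = 1.0 if math.isinf(self.theta) else 1.0 - math.exp(-a * self.theta)
        hi = a / (self.eta * b * decay)
        return lo, hi


def cauchy_W(a: float, schedule: ImpulseSchedule, t: float, s: float) -> float:
    """Transition factor ``W(t, s)`` of the linearized impulsive equation.

    Equals ``e^{-a(t-s)}`` times ``prod 1/(1+h_k)`` over jump times in
    ``[s, t)``: departing from the (left-continuous) pre-jump value at ``s``
    applies a jump sitting exactly at ``s``, while a jump exactly at ``t`` has
    not yet acted.  ``W(t, t) = 1``.
    """
    if s > t:
        raise ModelError(f"cauchy_W requires s <= t, got s={s} > t={t}")
    w = math.exp(-a * (t - s))
    if not schedule.is_empty:
        idx = schedule.points_in(s, t, closed="left")
        for k in idx:
            w /= 1.0 + schedule.coefficients[k, 0]
    return w


def logistic_ap_solution(params: ImpulsiveLogisticParams, t: float, tol: float = 1e-10) -> float:
    """Evaluate the positive recurrent orbit ``x*(t)`` in closed form.

    The improper integral is truncated at ``t - L`` with
    ``L = (ln(1/(a*tol)) + 5)/a`` (jump factors only shrink the integrand, so
    the tail is bounded by ``e^{-aL}/a``); below the truncation point the
    remaining mass is added analytically assuming no further jumps.  Between
    consecutive jump times the integrand is a pure exponential and integrates
    exactly.
    """
    a, b = params.a, params.b
    if params.delay != 0.0:
        raise ModelError("the closed-form orbit applies to the undelayed equation")
    if tol <= 0:
        raise ModelError("tol must be positive")
    if a <= 0:
        raise ModelError("truncation does not converge for a <= 0")
    L = (math.log(1.0 / (a * tol)) + 5.0) / a
    lo = t - L
    sched = params.schedule
    if sched.is_empty:
        inner = np.empty(0)
    else:
        idx = sched.points_in(lo, t, closed="left")
        inner = sched.points[idx]
        hs = sched.coefficients[idx, 0]
    # segment boundaries in s: lo < tau_(1) < ... < tau_(m) < t
    bounds = np.concatenate(([lo], inner, [t]))
    # suffix products: P_j = prod of 1/(1+h) over jumps >= bounds[j+1]
    m = inner.size
    total = 0.0
    if m:
        inv = 1.0 / (1.0 + hs)
        suffix = np.concatenate((np.cumprod(inv[::-1])[::-1], [1.0]))
    else:
        suffix = np.array([1.0])
    for j in range(bounds.size - 1):
        s0, s1 = bounds[j], bounds[j + 1]
        P = suffix[j] if m else 1.0
        seg = (math.exp(-a * (t - s1)) - math.exp(-a * (t - s0))) / a
        total += P * seg
    # analytic tail below the truncation point (no jumps assumed there)
    P_all = suffix[0] if m else 1.0
    total += P_all * math.exp(-a * L) / a
    u = b * total
    if u <= 0 or not math.isfinite(u):
        raise ModelError("orbit evaluation did not converge")
    return 1.0 / u


def window_product_extrema(
    schedule: ImpulseSchedule,
    tau: float,
    t_range: tuple[float, float] | None = None,
    species: int = 0,
) -> tuple[float, float]:
    """Exact inf/sup over ``t`` of ``prod_{tau_k in [t-tau, t)} 1/(1+h_k)``.

    The product is piecewise constant in ``t``; jump time ``tau_k`` belongs to
    the window exactly for ``t in (tau_k, tau_k + tau]``, so the extrema are
    attained on the partition induced by ``{tau_k} u {tau_k + tau}``.  ``t``
    ranges over ``[lo + tau, hi]`` of the schedule horizon by default, so the
    window always lies inside the generated schedule.
    """
    if tau < 0:
        raise ModelError("window length must be nonnegative")
    if tau == 0 or schedule.is_empty:
        return 1.0, 1.0
    lo, hi = schedule.horizon
    if t_range is None:
        t_range = (lo + tau, hi)
    t_lo, t_hi = t_range
    if t_hi < t_lo:
        raise ModelError("empty t-range for window scan")
    pts = schedule.points
    h = schedule.coefficients[:, species]
    logs = np.concatenate(([0.0], np.cumsum(-np.log1p(h))))

    def product(t: float) -> float:
        i0 = int(np.searchsorted(pts, t - tau, side="left"))
        i1 = int(np.searchsorted(pts, t, side="left"))
        return float(np.exp(logs[i1] - logs[i0]))

    brk = np.unique(np.concatenate((pts, pts + tau, [t_lo, t_hi])))
    brk = brk[(brk >= t_lo) & (brk <= t_hi)]
    candidates = np.concatenate((brk, 0.5 * (brk[:-1] + brk[1:]))) if brk.size > 1 else brk
    vals = [product(float(t)) for t in candidates]
    return float(min(vals)), float(max(vals))


def logistic_scalar_bounds(
    params: ImpulsiveLogisticParams,
    A: int | None = None,
    eta_pair_offset: int = 0,
) -> ScalarBoundSet:
    """All scalar bound constants for one delayed impulsive logistic problem.

    ``eta_pair_offset`` shifts the start index of the two-consecutive-jump
    products used for ``eta`` (the two printed conventions differ only by this
    shift and agree for stationary jump coefficients).
    """
    a, b, tau = params.a, params.b, params.delay
    sched = params.schedule
    h = sched.h(0)
    xi, eta = _h_extrema_products(h[eta_pair_offset:] if eta_pair_offset else h)
    if eta_pair_offset and h.size:
        # xi must still scan every jump, only eta pairs are shifted
        xi = _h_extrema_products(h)[0]
    theta = sched.theta()
    if A is None:
        A = schedule_A(sched)
    alpha = a - xi * A
    p_inf, p_sup = window_product_extrema(sched, tau)
    B = b * p_inf * math.exp(-a * tau)
    decay = 1.0 if math.isinf(theta) else 1.0 - math.exp(-a * theta)
    M = a / (eta * B * decay)
    if M <= 0 or not math.isfinite(M):
        raise ModelError(f"upper bound M={M} is not positive and finite")
    D = b * p_sup * math.exp(-(a - b * M) * tau)
    xi_p = max(xi, 0.0)  # see module docstring: negative xi must not inflate N
    N = (a - xi_p * A) / (math.exp(xi_p * A) * D)
    return ScalarBoundSet(xi=xi, alpha=alpha, theta=theta, eta=eta, A=int(A), B=B, D=D, M=M, N=N)
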