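"""Permanence and stability certification for the two-species model.

All suprema/infima over time are evaluated conservatively by interval
arithmetic on the certified coefficient bounds (the analytic ``inf``/``sup``
of each quasi-periodic coefficient); a dense-sampling refinement is available
as a diagnostic.  Conservative here means: the computed growth supremum
``r_i^u`` can only exceed the true one and the computed ``r_i^l`` can only
undershoot it, so a certificate that passes is genuinely valid.

Certified quantities per species ``i`` (``j`` the other species):

* ``r_i^u = sup_t |a_i0/m_i - c_i|`` — growth rate supremum,
* ``M_i  = r_i^u / (eta_i * B_i * (1 - e^{-r_i^u * theta}))`` — eventual upper
  bound, with ``B_i = inf_t a_ii^l * prod_{[t-tau_ii, t)}(1+h_ik)^{-1} *
  e^{-r_i^u tau_ii}``,
* ``r_i^l = inf_t [a_i0/(M_i + m_i) - a_ij*M_j - c_i]``,
* ``N_i  = (r_i^l - xi_i+*A) / (e^{xi_i+*A} * D_i)`` — eventual lower bound,
  with ``D_i = sup_t a_ii^u * prod(1+h_ik)^{-1} * e^{-(r_i^l - a_ii^u M_i)
  tau_ii}`` and ``xi_i+ = max(xi_i, 0)`` (the counting exponent is only valid
  in the lower bound through its nonnegative part; see the ``logistic``
  module docstring).

Certificate H1 requires ``r_i^l >= xi_i * A``; note that with nonnegative
jump coefficients ``xi_i <= 0``, so H1 can formally pass with ``r_i^l < 0``,
in which case the lower-bound comparison argument does not apply (its growth
rate must be positive) and ``N_i <= 0`` signals a vacuous lower bound.

Certificate H2 asks for positive weights ``lambda_1, lambda_2`` with
``lambda_1*alpha_1 > lambda_2*beta_1`` and ``lambda_2*alpha_2 >
lambda_1*beta_2``; feasibility reduces in closed form to ``alpha_i > 0`` and
``alpha_1*alpha_2 > beta_1*beta_2``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np

from .logistic import window_product_extrema
from .model import ModelError, SchoenerModel, schedule_A

__all__ = [
    "PermanenceBounds",
    "StabilityReport",
    "growth_suprema",
    "permanence_bounds",
    "check_H1",
    "stability_constants",
    "check_H2",
]


@dataclass(frozen=True)
class PermanenceBounds:
    r1_u: float
    r2_u: float
    r1_l: float
    r2_l: float
    B1: float
    B2: float
    D1: float
    D2: float
    eta1: float
    eta2: float
    xi1: float
    xi2: float
    theta: float
    A: int
    M1: float
    M2: float
    N1: float
    N2: float

    def M(self, i: int) -> float:
        return self.M1 if i == 1 else self.M2

    def N(self, i: int) -> float:
        return self.N1 if i == 1 else self.N2

    def with_overrides(self, **kwargs) -> "PermanenceBounds":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StabilityReport:
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    feasible: bool
    lambda1: float | None
    lambda2: float | None
    Theta: float | None
    ratio_interval: tuple[float, float] | None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["ratio_interval"] is not None:
            d["ratio_interval"] = list(d["ratio_interval"])
        return d


def _ratio_interval(num, den) -> tuple[float, float]:
    """Interval bounds of f/g from positive interval bounds of f and g."""
    (f_lo, f_hi), (g_lo, g_hi) = num, den
    if g_lo <= 0:
        raise ModelError("denominator interval must be positive")
    return f_lo / g_hi, f_hi / g_lo


def growth_suprema(model: SchoenerModel, mode: str = "analytic", samples: int = 200_001):
    """Conservative ``sup_t |a_i0(t)/m_i(t) - c_i(t)|`` for both species."""
    if mode == "sampled":
        t = np.linspace(0.0, 1000.0, samples)
        r1 = float(np.max(np.abs(model.a10(t) / model.m1(t) - model.c1(t))))
        r2 = float(np.max(np.abs(model.a20(t) / model.m2(t) - model.c2(t))))
        return r1, r2
    out = []
    for a0, m, c in ((model.a10, model.m1, model.c1), (model.a20, model.m2, model.c2)):
        lo, hi = _ratio_interval((a0.inf, a0.sup), (m.inf, m.sup))
        d_lo, d_hi = lo - c.sup, hi - c.inf
        out.append(max(abs(d_lo), abs(d_hi)))
    return out[0], out[1]


def permanence_bounds(model: SchoenerModel) -> PermanenceBounds:
    """Compute every constant of the permanence certificate for ``model``."""
    r1_u, r2_u = growth_suprema(model)
    if r1_u <= 0 or r2_u <= 0:
        raise ModelError("degenerate model: growth suprema must be positive")
    sched = model.schedule
    theta = sched.theta()
    A = schedule_A(sched)
    xi1, eta1 = model.xi_eta(1)
    xi2, eta2 = model.xi_eta(2)

    def upper(i, r_u, a_ii, xi, eta):
        tau_ii = model.delay(i, i)
        p_inf, p_sup = window_product_extrema(sched, tau_ii, species=i - 1)
        B = a_ii.inf * p_inf * math.exp(-r_u * tau_ii)
        decay = 1.0 if math.isinf(theta) else 1.0 - math.exp(-r_u * theta)
        M = r_u / (eta * B * decay)
        if M <= 0 or not math.isfinite(M):
            raise ModelError(f"upper bound M{i}={M} is not positive and finite")
        return B, M, p_sup

    B1, M1, p_sup1 = upper(1, r1_u, model.a11, xi1, eta1)
    B2, M2, p_sup2 = upper(2, r2_u, model.a22, xi2, eta2)

    r1_l = model.a10.inf / (M1 + model.m1.sup) - model.a12.sup * M2 - model.c1.sup
    r2_l = model.a20.inf / (M2 + model.m2.sup) - model.a21.sup * M1 - model.c2.sup

    def lower(i, r_l, a_ii, M, p_sup, xi):
        tau_ii = model.delay(i, i)
        D = a_ii.sup * p_sup * math.exp(-(r_l - a_ii.sup * M) * tau_ii)
        xi_p = max(xi, 0.0)
        N = (r_l - xi_p * A) / (math.exp(xi_p * A) * D)
        return D, N

    D1, N1 = lower(1, r1_l, model.a11, M1, p_sup1, xi1)
    D2, N2 = lower(2, r2_l, model.a22, M2, p_sup2, xi2)

    return PermanenceBounds(
        r1_u=r1_u, r2_u=r2_u, r1_l=r1_l, r2_l=r2_l,
        B1=B1, B2=B2, D1=D1, D2=D2,
        eta1=eta1, eta2=eta2, xi1=xi1, xi2=xi2,
        theta=theta, A=A, M1=M1, M2=M2, N1=N1, N2=N2,
    )


def check_H1(bounds: PermanenceBounds) -> tuple[bool, tuple[float, float]]:
    """Certificate H1: ``r_i^l >= xi_i * A`` for both species.

    Returns ``(holds, margins)`` with ``margins = r_i^l - xi_i*A``.  Callers
    that rely on the lower bounds ``N_i`` should additionally require
    ``r_i^l > 0`` (see module docstring).
    """
    m1 = bounds.r1_l - bounds.xi1 * bounds.A
    m2 = bounds.r2_l - bounds.xi2 * bounds.A
    return (m1 >= 0.0 and m2 >= 0.0), (m1, m2)


def stability_constants(
    model: SchoenerModel,
    bounds: PermanenceBounds,
) -> tuple[float, float, float, float]:
    """The four contraction/coupling constants of the stability certificate.

    ``alpha_i`` collects the contraction supplied by species ``i``'s own
    dynamics minus the delay-induced self-coupling; ``beta_i`` the cross
    coupling exerted on it.  All delay terms vanish as the delays go to zero.
    """
    M1, M2, N1, N2 = bounds.M1, bounds.M2, bounds.N1, bounds.N2
    if N1 <= 0 or N2 <= 0:
        raise ModelError("stability constants require positive lower bounds N_i")
    d = model.delay
    a10u, a10l = model.a10.sup, model.a10.inf
    a20u, a20l = model.a20.sup, model.a20.inf
    a11u, a11l = model.a11.sup, model.a11.inf
    a22u, a22l = model.a22.sup, model.a22.inf
    a12u, a21u = model.a12.sup, model.a21.sup
    m1u, m1l = model.m1.sup, model.m1.inf
    m2u, m2l = model.m2.sup, model.m2.inf

    q1 = (N1 + m1l) ** 2
    q2 = (N2 + m2l) ** 2
    alpha1 = (
        a10l * N1 / (M1 + m1u) ** 2
        + a11l * N1
        - (math.sqrt(d(1, 0)) * a10u * M1 / q1) ** 2
        - (d(1, 0) + d(1, 1)) * a10u * a11u * M1**2 / q1
        - d(1, 1) * a11u**2 * M1**2
    )
    alpha2 = (
        a20l * N2 / (M2 + m2u) ** 2
        + a22l * N2
        - (math.sqrt(d(2, 0)) * a20u * M2 / q2) ** 2
        - (d(2, 0) + d(2, 2)) * a20u * a22u * M2**2 / q2
        - d(2, 2) * a22u**2 * M2**2
    )
    beta1 = (
        d(2, 0) * a20u * a21u * M1 * M2 / q2
        + d(2, 2) * a21u * a22u * M1 * M2
        + a21u * M1
    )
    beta2 = (
        d(1, 0) * a10u * a12u * M1 * M2 / q1
        + d(1, 1) * a11u * a12u * M1 * M2
        + a12u * M2
    )
    return alpha1, alpha2, beta1, beta2


def check_H2(alpha1: float, alpha2: float, beta1: float, beta2: float) -> StabilityReport:
    """Closed-form feasibility of the weighted contraction inequalities.

    Feasible iff ``alpha_1, alpha_2 > 0`` and ``alpha_1*alpha_2 >
    beta_1*beta_2``; the admissible weight ratio ``lambda_1/lambda_2`` is the
    open interval ``(beta_1/alpha_1, alpha_2/beta_2)``.  The returned weights
    take the ratio at the geometric mean of the interval endpoints (with
    sensible fallbacks when an endpoint is 0 or infinite) and ``lambda_2 = 1``.
    """
    if beta1 < 0 or beta2 < 0:
        raise ModelError("beta constants must be nonnegative")
    feasible = alpha1 > 0 and alpha2 > 0 and alpha1 * alpha2 > beta1 * beta2
    if not feasible:
        return StabilityReport(alpha1, alpha2, beta1, beta2, False, None, None, None, None)
    lo = beta1 / alpha1
    hi = alpha2 / beta2 if beta2 > 0 else math.inf
    if lo > 0 and math.isfinite(hi):
        ratio = math.sqrt(lo * hi)
    elif lo > 0:
        ratio = 2.0 * lo
    elif math.isfinite(hi):
        ratio = 0.5 * hi
    else:
        ratio = 1.0
    lam1, lam2 = ratio, 1.0
    Theta = min(lam1 * alpha1 - lam2 * beta1, lam2 * alpha2 - lam1 * beta2)
    return StabilityReport(
        alpha1, alpha2, beta1, beta2, True, lam1, lam2, Theta, (lo, hi)
    )
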