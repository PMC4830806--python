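"""Model ingredients: quasi-periodic coefficients, impulse schedules, and the
two-species competition model they parameterize.

Coefficients are finite trigonometric sums ``c + sum_k A_k w(omega_k t + phi_k)``
with ``w`` either sine or cosine.  Their certified bounds
``[c - sum|A_k|, c + sum|A_k|]`` are what every theory computation consumes;
empirical (sampled) extrema are available as a diagnostic only.

Impulse schedules are finite, strictly increasing point sets with per-species
multiplicative jump coefficients ``h >= 0`` (the state jumps by a factor
``1 + h`` at each point).  Generated schedules have the form
``tau_k = k*P + a*sin(w*k)`` which keeps the family of difference sequences
uniformly recurrent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Harmonic",
    "QuasiPeriodicCoefficient",
    "ImpulseSchedule",
    "SchoenerModel",
    "coef_eval",
    "coef_bounds",
    "schedule_generate",
    "schedule_theta",
    "schedule_A",
    "random_weak_competition_model",
]


class ModelError(ValueError):
    """Raised for invalid model ingredients (nonpositive coefficients, bad schedules)."""


@dataclass(frozen=True)
class Harmonic:
    """One trigonometric term ``amplitude * waveform(angular_frequency*t + phase)``."""

    amplitude: float
    angular_frequency: float
    phase: float = 0.0
    waveform: str = "cos"

    def __post_init__(self) -> None:
        if self.waveform not in ("sin", "cos"):
            raise ModelError(f"waveform must be 'sin' or 'cos', got {self.waveform!r}")

    def __call__(self, t):
        arg = self.angular_frequency * np.asarray(t, dtype=float) + self.phase
        fn = np.sin if self.waveform == "sin" else np.cos
        return self.amplitude * fn(arg)


@dataclass(frozen=True)
class QuasiPeriodicCoefficient:
    """Bounded time-varying coefficient: constant plus a finite harmonic sum."""

    constant_term: float
    harmonics: tuple[Harmonic, ...] = ()

    @classmethod
    def constant(cls, value: float) -> "QuasiPeriodicCoefficient":
        return cls(constant_term=float(value))

    @classmethod
    def single(
        cls,
        constant: float,
        amplitude: float,
        angular_frequency: float,
        phase: float = 0.0,
        waveform: str = "cos",
    ) -> "QuasiPeriodicCoefficient":
        return cls(float(constant), (Harmonic(amplitude, angular_frequency, phase, waveform),))

    def __call__(self, t):
        if np.ndim(t) == 0:  # fast scalar path (hot loop of the integrator)
            t = float(t)
            out = self.constant_term
            for h in self.harmonics:
                arg = h.angular_frequency * t + h.phase
                out += h.amplitude * (math.sin(arg) if h.waveform == "sin" else math.cos(arg))
            return out
        out = np.full_like(np.asarray(t, dtype=float), self.constant_term)
        for h in self.harmonics:
            out = out + h(t)
        return out

    @property
    def amplitude_sum(self) -> float:
        return float(sum(abs(h.amplitude) for h in self.harmonics))

    @property
    def inf(self) -> float:
        return self.constant_term - self.amplitude_sum

    @property
    def sup(self) -> float:
        return self.constant_term + self.amplitude_sum

    def bounds(
        self,
        mode: str = "analytic",
        horizon: tuple[float, float] = (0.0, 1000.0),
        samples: int = 200_001,
    ) -> tuple[float, float]:
        """Certified (analytic) or empirical (sampled) inf/sup of the coefficient.

        The sampled interval is always contained in the analytic one.
        """
        if mode == "analytic":
            return (self.inf, self.sup)
        if mode == "sampled":
            t = np.linspace(horizon[0], horizon[1], samples)
            vals = self(t)
            return (float(vals.min()), float(vals.max()))
        raise ModelError(f"unknown bounds mode {mode!r}")

    def require_positive(self, name: str = "coefficient") -> None:
        if self.inf <= 0.0:
            raise ModelError(
                f"{name} must be positive: analytic inf {self.inf} <= 0 "
                f"(constant {self.constant_term}, amplitude sum {self.amplitude_sum})"
            )


def coef_eval(coef: QuasiPeriodicCoefficient, t) -> float:
    """Evaluate a coefficient at time ``t``."""
    return coef(t)


def coef_bounds(
    coef: QuasiPeriodicCoefficient,
    mode: str = "analytic",
    horizon: tuple[float, float] = (0.0, 1000.0),
    samples: int = 200_001,
) -> tuple[float, float]:
    """Inf/sup of a coefficient (see :meth:`QuasiPeriodicCoefficient.bounds`)."""
    return coef.bounds(mode=mode, horizon=horizon, samples=samples)


@dataclass(frozen=True)
class ImpulseSchedule:
    """Finite, strictly increasing jump times with per-species coefficients.

    ``coefficients`` has shape ``(len(points), n_species)``; entry ``[k, i]``
    is the jump coefficient ``h`` of species ``i`` at ``points[k]`` (the state
    is multiplied by ``1 + h``).  All suprema/infima over the index set are
    taken over the generated window, which is the whole (finite) horizon.
    """

    points: np.ndarray
    coefficients: np.ndarray
    horizon: tuple[float, float]
    base_period: float = 0.0
    jitter_amplitude: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.ndim == 1:
            coeffs = coeffs[:, None]
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "coefficients", coeffs)
        if pts.size:
            gaps = np.diff(pts)
            if gaps.size and gaps.min() <= 0.0:
                raise ModelError("impulse points must be strictly increasing")
            if coeffs.shape[0] != pts.size:
                raise ModelError("coefficients must align with points")
            if np.any(1.0 + coeffs <= 0.0):
                raise ModelError("every jump must satisfy 1 + h > 0")

    @property
    def n_species(self) -> int:
        return int(self.coefficients.shape[1]) if self.points.size else 1

    @property
    def is_empty(self) -> bool:
        return self.points.size == 0

    @classmethod
    def empty(cls, horizon=(0.0, 0.0), n_species: int = 1) -> "ImpulseSchedule":
        return cls(
            points=np.empty(0),
            coefficients=np.empty((0, n_species)),
            horizon=tuple(horizon),
        )

    def species(self, i: int) -> "ImpulseSchedule":
        """Single-species view (for the scalar comparison theory)."""
        if self.is_empty:
            return ImpulseSchedule.empty(self.horizon)
        return ImpulseSchedule(
            points=self.points,
            coefficients=self.coefficients[:, i : i + 1],
            horizon=self.horizon,
            base_period=self.base_period,
            jitter_amplitude=self.jitter_amplitude,
        )

    def h(self, i: int = 0) -> np.ndarray:
        return self.coefficients[:, i] if not self.is_empty else np.empty(0)

    def theta(self) -> float:
        """Minimal consecutive gap; +inf for schedules with fewer than two points."""
        if self.points.size < 2:
            return math.inf
        return float(np.diff(self.points).min())

    def points_in(self, lo: float, hi: float, closed: str = "left"):
        """Indices of points in a half-open window ([lo, hi) by default)."""
        if self.is_empty:
            return np.empty(0, dtype=int)
        if closed == "left":  # [lo, hi)
            i0 = int(np.searchsorted(self.points, lo, side="left"))
            i1 = int(np.searchsorted(self.points, hi, side="left"))
        elif closed == "right":  # (lo, hi]
            i0 = int(np.searchsorted(self.points, lo, side="right"))
            i1 = int(np.searchsorted(self.points, hi, side="right"))
        elif closed == "open":  # (lo, hi)
            i0 = int(np.searchsorted(self.points, lo, side="right"))
            i1 = int(np.searchsorted(self.points, hi, side="left"))
        else:
            raise ModelError(f"unknown window convention {closed!r}")
        return np.arange(i0, i1)


def schedule_generate(
    base_period: float,
    jitter_amplitude: float,
    jitter_frequency: float,
    h1: float,
    h2: float | None = None,
    horizon: tuple[float, float] = (0.0, 100.0),
    seed: int | None = None,
) -> ImpulseSchedule:
    """Deterministic quasi-periodic schedule ``tau_k = k*P + a*sin(w*k)``.

    ``seed`` is accepted for interface stability but unused: the jitter is a
    deterministic sinusoid in ``k``, which keeps the difference sequences
    uniformly recurrent by construction.
    """
    if base_period <= 0:
        raise ModelError("base_period must be positive")
    if jitter_amplitude < 0 or 2 * jitter_amplitude >= base_period:
        raise ModelError("need base_period > 2*jitter_amplitude >= 0")
    hs = [h1] if h2 is None else [h1, h2]
    for h in hs:
        if h < 0:
            raise ModelError("jump coefficients must be nonnegative")
    lo, hi = float(horizon[0]), float(horizon[1])
    # tau_k in [lo, hi] requires k*P within jitter_amplitude of the interval
    k_min = math.floor((lo - jitter_amplitude) / base_period) - 1
    k_max = math.ceil((hi + jitter_amplitude) / base_period) + 1
    ks = np.arange(k_min, k_max + 1)
    pts = ks * base_period
    if jitter_amplitude > 0:
        pts = pts + jitter_amplitude * np.sin(jitter_frequency * ks)
    mask = (pts >= lo) & (pts <= hi)
    pts = pts[mask]
    if pts.size >= 2 and np.diff(pts).min() <= 0:
        raise ModelError("generated schedule has nonpositive gaps")
    coeffs = np.tile(np.asarray(hs, dtype=float), (pts.size, 1))
    return ImpulseSchedule(
        points=pts,
        coefficients=coeffs,
        horizon=(lo, hi),
        base_period=float(base_period),
        jitter_amplitude=float(jitter_amplitude),
    )


def schedule_theta(schedule: ImpulseSchedule) -> float:
    """Minimal consecutive gap of the schedule (+inf when fewer than two points)."""
    return schedule.theta()


def schedule_A(schedule: ImpulseSchedule, horizon: tuple[float, float] | None = None) -> int:
    """Minimal nonnegative integer ``A`` with ``count(s,t) <= A*(t-s) + A``.

    ``count(s,t)`` is the number of schedule points in the open window
    ``(s, t)``.  The binding windows shrink onto point pairs: for points
    ``tau_i <= tau_j`` the constraint in the limit is
    ``(j - i + 1) <= A*(tau_j - tau_i) + A``, so the exact answer is the
    ceiling of the worst ratio ``(j - i + 1)/(tau_j - tau_i + 1)`` over all
    pairs inside the horizon.
    """
    if schedule.is_empty:
        return 0
    pts = schedule.points
    if horizon is not None:
        lo, hi = horizon
        pts = pts[(pts >= lo) & (pts <= hi)]
    n = pts.size
    if n == 0:
        return 0
    best = 0
    for i in range(n):
        # count/(gap+1) is maximized at the densest clusters; full O(n^2) scan
        counts = np.arange(1, n - i + 1, dtype=float)
        gaps = pts[i:] - pts[i]
        ratios = counts / (gaps + 1.0)
        m = ratios.max()
        if m > best:
            best = m
    return int(math.ceil(best - 1e-12))


def _h_extrema_products(h: np.ndarray) -> tuple[float, float]:
    """(xi, eta) of a single-species jump sequence.

    ``xi = ln sup_k 1/(1+h_k)`` (0 for an empty schedule) and ``eta`` is the
    infimum over windows of at most two consecutive jump factors
    ``prod 1/(1+h)``, capped at 1.
    """
    if h.size == 0:
        return 0.0, 1.0
    inv = 1.0 / (1.0 + h)
    xi = float(np.log(inv.max()))
    eta = min(1.0, float(inv.min()))
    if h.size >= 2:
        eta = min(eta, float((inv[:-1] * inv[1:]).min()))
    return xi, eta


@dataclass(frozen=True)
class SchoenerModel:
    """Full parameterization of the impulsive, delayed two-species model.

    Dynamics (between impulses, all arguments retarded by the given delays)::

        x1' = x1 * [ a10/(x1(t-tau10) + m1) - a11*x1(t-tau11) - a12*x2(t-tau12) - c1 ]
        x2' = x2 * [ a20/(x2(t-tau20) + m2) - a21*x1(t-tau21) - a22*x2(t-tau22) - c2 ]

    and at each schedule point ``x_i`` jumps to ``(1 + h_i) * x_i``.
    """

    a10: QuasiPeriodicCoefficient
    a20: QuasiPeriodicCoefficient
    a11: QuasiPeriodicCoefficient
    a12: QuasiPeriodicCoefficient
    a21: QuasiPeriodicCoefficient
    a22: QuasiPeriodicCoefficient
    m1: QuasiPeriodicCoefficient
    m2: QuasiPeriodicCoefficient
    c1: QuasiPeriodicCoefficient
    c2: QuasiPeriodicCoefficient
    delays: dict = field(default_factory=dict)  # keys "tau10".."tau22"
    schedule: ImpulseSchedule = field(default_factory=lambda: ImpulseSchedule.empty(n_species=2))

    _DELAY_KEYS = ("tau10", "tau11", "tau12", "tau20", "tau21", "tau22")
    _POSITIVE = ("a10", "a20", "a11", "a12", "a21", "a22", "m1", "m2", "c1", "c2")

    def __post_init__(self) -> None:
        delays = {k: float(self.delays.get(k, 0.0)) for k in self._DELAY_KEYS}
        for k, v in delays.items():
            if v < 0:
                raise ModelError(f"delay {k} must be nonnegative")
        object.__setattr__(self, "delays", delays)
        for name in self._POSITIVE:
            getattr(self, name).require_positive(name)
        if self.schedule.n_species != 2 and not self.schedule.is_empty:
            raise ModelError("model schedule must carry two species")

    def delay(self, i: int, j: int) -> float:
        return self.delays[f"tau{i}{j}"]

    @property
    def tau_max(self) -> float:
        return 2.0 * max(self.delays.values())

    def coefficient(self, name: str) -> QuasiPeriodicCoefficient:
        return getattr(self, name)

    def xi_eta(self, i: int) -> tuple[float, float]:
        """(xi_i, eta_i) of species ``i`` (1-based) from the schedule."""
        return _h_extrema_products(self.schedule.h(i - 1))


def random_weak_competition_model(
    seed: int,
    horizon: tuple[float, float] = (0.0, 200.0),
) -> SchoenerModel:
    """Seeded generator of weak-competition scenarios.

    Parameter ranges are chosen so that the permanence certificate is
    typically strict (the growth infimum ``r_i^l`` is positive): weak
    interspecific coupling, mild impulses, small delays, and gentle
    quasi-periodic forcing.  Rejection-samples until the certificate holds.
    """
    from .theory import check_H1, permanence_bounds  # local import, avoids cycle

    rng = np.random.default_rng(seed)
    for _ in range(64):
        model = _draw_model(rng, horizon)
        try:
            bounds = permanence_bounds(model)
        except ModelError:
            continue
        holds, _ = check_H1(bounds)
        if holds and bounds.r1_l > 0 and bounds.r2_l > 0 and bounds.N1 > 0 and bounds.N2 > 0:
            return model
    raise ModelError(f"could not draw a certified weak-competition model for seed {seed}")


def _draw_model(rng: np.random.Generator, horizon) -> SchoenerModel:
    def qp(lo, hi, max_amp, freq_scale=1.0):
        const = rng.uniform(lo, hi)
        amp = rng.uniform(0.0, max_amp)
        freq = rng.uniform(0.5, 2.0) * freq_scale
        phase = rng.uniform(0.0, 2 * math.pi)
        wave = "sin" if rng.random() < 0.5 else "cos"
        if amp == 0.0:
            return QuasiPeriodicCoefficient.constant(const)
        return QuasiPeriodicCoefficient.single(const, amp, freq, phase, wave)

    schedule = schedule_generate(
        base_period=rng.uniform(8.0, 12.0),
        jitter_amplitude=rng.uniform(0.0, 0.5),
        jitter_frequency=math.sqrt(2.0),
        h1=rng.uniform(0.0, 0.08),
        h2=rng.uniform(0.0, 0.08),
        horizon=horizon,
    )
    delays = {
        "tau10": rng.uniform(0.0, 3e-4),
        "tau11": rng.uniform(0.0, 3e-4),
        "tau12": rng.uniform(0.0, 3e-4),
        "tau20": rng.uniform(0.0, 3e-4),
        "tau21": rng.uniform(0.0, 3e-4),
        "tau22": rng.uniform(0.0, 3e-4),
    }
    return SchoenerModel(
        a10=qp(0.95, 1.05, 0.02),
        a20=qp(0.95, 1.05, 0.02),
        a11=qp(0.34, 0.38, 0.02, freq_scale=math.sqrt(3.0)),
        a22=qp(0.34, 0.38, 0.02, freq_scale=math.sqrt(3.0)),
        a12=QuasiPeriodicCoefficient.constant(rng.uniform(5e-5, 2e-4)),
        a21=QuasiPeriodicCoefficient.constant(rng.uniform(5e-5, 2e-4)),
        m1=qp(1.9, 2.1, 0.02),
        m2=qp(1.9, 2.1, 0.02),
        c1=qp(0.26, 0.28, 5e-5, freq_scale=math.sqrt(2.0)),
        c2=qp(0.26, 0.28, 5e-5, freq_scale=math.sqrt(2.0)),
        delays=delays,
        schedule=schedule,
    )
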