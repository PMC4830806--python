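import math

import numpy as np
import pytest

import schoenersim as ss
from schoenersim.model import ModelError, QuasiPeriodicCoefficient as QPC


def h2_grid_oracle(a1, a2, b1, b2, ratios=None):
    """Oracle: brute-force search over weight ratios lambda1/lambda2."""
    if ratios is None:
        ratios = np.logspace(-6, 6, 4001)
    ok = (ratios * a1 > b1) & (a2 > ratios * b2)
    return bool(ok.any())


class TestGrowthSuprema:
    def test_interval_case(self):
        C = QPC.constant
        model = ss.SchoenerModel(
            a10=C(1.0), a20=C(1.0), a11=C(0.35), a22=C(0.35), a12=C(1e-4), a21=C(1e-4),
            m1=C(2.0), m2=C(2.0),
            c1=QPC.single(0.30005, 0.00005, math.sqrt(2), waveform="sin"), c2=C(0.3),
        )
        r1, _ = ss.growth_suprema(model)
        assert r1 == pytest.approx(0.2, abs=1e-12)
        # dense sampling oracle agrees (and can only be smaller)
        r1s, _ = ss.growth_suprema(model, mode="sampled", samples=300_001)
        assert r1s <= r1 + 1e-12
        assert r1s == pytest.approx(r1, abs=1e-6)

    def test_zero_case(self, make_constant_model):
        model = make_constant_model(a10=2.0, m1=2.0, c1=1.0)
        r1, _ = ss.growth_suprema(model)
        assert r1 == pytest.approx(0.0, abs=1e-14)

    def test_constant_case(self, make_constant_model):
        model = make_constant_model(a10=2.0, m1=1.0, c1=0.5)
        r1, _ = ss.growth_suprema(model)
        assert r1 == pytest.approx(1.5, abs=1e-14)


class TestPermanenceBounds:
    def test_classical_reduction(self, make_constant_model):
        model = make_constant_model()
        b = ss.permanence_bounds(model)
        r_u = abs(1.0 / 2.0 - 0.3)
        assert b.xi1 == 0.0 and b.eta1 == 1.0 and b.A == 0
        assert math.isinf(b.theta)
        assert b.B1 == pytest.approx(0.35)
        assert b.D1 == pytest.approx(0.35)
        assert b.M1 == pytest.approx(r_u / 0.35, rel=1e-12)
        assert b.r1_l == pytest.approx(1.0 / (b.M1 + 2.0) - 1e-4 * b.M2 - 0.3, rel=1e-12)
        assert b.N1 == pytest.approx(b.r1_l / 0.35, rel=1e-12)

    def test_symmetry(self, make_constant_model):
        sched = ss.schedule_generate(5, 0, 0, 0.3, 0.3, (0, 100))
        delays = {k: 1e-4 for k in ("tau10", "tau11", "tau12", "tau20", "tau21", "tau22")}
        model = make_constant_model(schedule=sched, delays=delays)
        b = ss.permanence_bounds(model)
        assert b.M1 == pytest.approx(b.M2, rel=1e-14)
        assert b.N1 == pytest.approx(b.N2, rel=1e-14)

    def test_demo_scenario_constants(self, demo_model):
        # values recomputed from the formulas (not the source's inconsistent
        # printed intermediates): theta = 5, A = 1, M1 ~ 3.56, r1_l < 0
        b = ss.permanence_bounds(demo_model)
        assert b.theta == 5.0 and b.A == 1
        assert b.r1_u == pytest.approx(0.2, abs=1e-12)
        assert b.M1 == pytest.approx(3.5595, rel=1e-3)
        assert b.M2 == pytest.approx(2.8940, rel=1e-3)
        assert b.r1_l < 0  # printed example claims >= 0.03; not reproducible
        holds, margins = ss.check_H1(b)
        assert holds  # formally: r_l >= xi*A with xi < 0
        assert b.N1 < 0  # the lower bound is vacuous, honestly signalled

    def test_degenerate_model_rejected(self, make_constant_model):
        model = make_constant_model(a10=0.6, m1=2.0, c1=0.3, a20=0.6, m2=2.0, c2=0.3)
        with pytest.raises(ModelError):
            ss.permanence_bounds(model)


class TestCheckH1:
    def test_zero_growth_holds_with_negative_xi(self, certified_bounds):
        b = certified_bounds.with_overrides(r1_l=0.0, r2_l=0.0)
        holds, margins = ss.check_H1(b)
        assert holds
        assert margins[0] == pytest.approx(-b.xi1 * b.A)

    def test_failure_margin(self, certified_bounds):
        b = certified_bounds.with_overrides(r1_l=-0.1, xi1=0.0)
        holds, margins = ss.check_H1(b)
        assert not holds
        assert margins[0] == pytest.approx(-0.1)


class TestStabilityConstants:
    def alpha_beta_oracle(self, model, M1, M2, N1, N2):
        """Independent re-implementation of the four constants."""
        d = model.delay
        s = lambda c: c.sup
        i = lambda c: c.inf
        q1 = (N1 + i(model.m1)) ** 2
        q2 = (N2 + i(model.m2)) ** 2
        a1 = (
            i(model.a10) * N1 / (M1 + s(model.m1)) ** 2 + i(model.a11) * N1
            - d(1, 0) * (s(model.a10) * M1) ** 2 / q1**2
            - (d(1, 0) + d(1, 1)) * s(model.a10) * s(model.a11) * M1**2 / q1
            - d(1, 1) * s(model.a11) ** 2 * M1**2
        )
        a2 = (
            i(model.a20) * N2 / (M2 + s(model.m2)) ** 2 + i(model.a22) * N2
            - d(2, 0) * (s(model.a20) * M2) ** 2 / q2**2
            - (d(2, 0) + d(2, 2)) * s(model.a20) * s(model.a22) * M2**2 / q2
            - d(2, 2) * s(model.a22) ** 2 * M2**2
        )
        b1 = (
            d(2, 0) * s(model.a20) * s(model.a21) * M1 * M2 / q2
            + d(2, 2) * s(model.a21) * s(model.a22) * M1 * M2
            + s(model.a21) * M1
        )
        b2 = (
            d(1, 0) * s(model.a10) * s(model.a12) * M1 * M2 / q1
            + d(1, 1) * s(model.a11) * s(model.a12) * M1 * M2
            + s(model.a12) * M2
        )
        return a1, a2, b1, b2

    def test_zero_delay_reduction(self, make_constant_model, certified_bounds):
        model = make_constant_model()
        b = certified_bounds.with_overrides(M1=0.6, M2=0.5, N1=0.2, N2=0.25)
        a1, a2, b1, b2 = ss.stability_constants(model, b)
        assert a1 == pytest.approx(1.0 * 0.2 / (0.6 + 2.0) ** 2 + 0.35 * 0.2, rel=1e-14)
        assert b1 == pytest.approx(1e-4 * 0.6, rel=1e-14)
        assert b2 == pytest.approx(1e-4 * 0.5, rel=1e-14)

    def test_beta2_vanishes(self, make_constant_model, certified_bounds):
        model = make_constant_model(a12=1e-300)  # a12 -> 0 with zero delays
        b = certified_bounds.with_overrides(M1=0.6, M2=0.5, N1=0.2, N2=0.25)
        _, _, _, b2 = ss.stability_constants(model, b)
        assert b2 == pytest.approx(0.0, abs=1e-290)

    def test_demo_with_supplied_bounds(self, demo_model):
        # externally supplied M, N (the source's undefined starred values)
        base = ss.permanence_bounds(demo_model)
        b = base.with_overrides(M1=0.7256, M2=0.5421, N1=0.01, N2=0.01)
        a1, a2, b1, b2 = ss.stability_constants(demo_model, b)
        oracle = self.alpha_beta_oracle(demo_model, 0.7256, 0.5421, 0.01, 0.01)
        assert (a1, a2, b1, b2) == pytest.approx(oracle, rel=1e-12)
        assert a1 > 0 and a2 > 0
        assert max(b1, b2) < min(a1, a2)

    def test_matches_oracle_random(self):
        for seed in range(3):
            model = ss.random_weak_competition_model(seed + 20, horizon=(0.0, 60.0))
            b = ss.permanence_bounds(model)
            got = ss.stability_constants(model, b)
            want = self.alpha_beta_oracle(model, b.M1, b.M2, b.N1, b.N2)
            assert got == pytest.approx(want, rel=1e-12)

    def test_requires_positive_N(self, demo_model):
        base = ss.permanence_bounds(demo_model)
        with pytest.raises(ModelError):
            ss.stability_constants(demo_model, base)  # N1 < 0 for this scenario


class TestCheckH2:
    def test_worked_instance(self):
        rep = ss.check_H2(0.03, 0.02, 7e-5, 7e-5)
        assert rep.feasible
        # lambda1 = lambda2 = 1 also satisfies both inequalities
        assert 1.0 * 0.03 > 1.0 * 7e-5 and 1.0 * 0.02 > 1.0 * 7e-5
        assert rep.ratio_interval[0] < 1.0 < rep.ratio_interval[1]
        assert rep.lambda1 * rep.alpha1 > rep.lambda2 * rep.beta1
        assert rep.lambda2 * rep.alpha2 > rep.lambda1 * rep.beta2
        assert rep.Theta > 0

    def test_infeasible(self):
        rep = ss.check_H2(1.0, 1.0, 2.0, 2.0)
        assert not rep.feasible
        assert not h2_grid_oracle(1.0, 1.0, 2.0, 2.0)

    def test_ratio_interval(self):
        rep = ss.check_H2(2.0, 1.0, 1.0, 1.9)
        assert rep.feasible
        assert rep.ratio_interval == pytest.approx((0.5, 1 / 1.9))
        assert h2_grid_oracle(2.0, 1.0, 1.0, 1.9)

    def test_zero_betas(self):
        rep = ss.check_H2(0.5, 0.5, 0.0, 0.0)
        assert rep.feasible and rep.lambda1 > 0

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(0)
        n = 0
        while n < 300:
            a1, a2 = rng.uniform(1e-3, 1.0, 2)
            b1, b2 = rng.uniform(0.0, 1.0, 2) * (rng.random(2) < 0.9)
            lhs, rhs = a1 * a2, b1 * b2
            margin = abs(math.log((lhs + 1e-300) / (rhs + 1e-300)))
            if margin < 0.05:
                continue  # skip hairline cases below the grid's resolution
            rep = ss.check_H2(a1, a2, b1, b2)
            assert rep.feasible == h2_grid_oracle(a1, a2, b1, b2)
            n += 1

    def test_negative_beta_rejected(self):
        with pytest.raises(ModelError):
            ss.check_H2(1.0, 1.0, -0.1, 0.0)


def test_classical_limit_full_pipeline(make_constant_model):
    """No impulses + zero delays: the pipeline reproduces the continuous,
    undelayed bound constants computed by hand."""
    model = make_constant_model(a10=1.0, m1=2.0, a11=0.4, c1=0.25,
                                a20=1.0, m2=2.0, a22=0.4, c2=0.25, a12=1e-4, a21=1e-4)
    b = ss.permanence_bounds(model)
    r_u = 0.25
    M = r_u / 0.4
    r_l = 1.0 / (M + 2.0) - 1e-4 * M - 0.25
    assert b.M1 == pytest.approx(M, rel=1e-14)
    assert b.r1_l == pytest.approx(r_l, rel=1e-12)
    assert b.N1 == pytest.approx(r_l / 0.4, rel=1e-12)
    holds, _ = ss.check_H1(b)
    assert holds and b.N1 > 0
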