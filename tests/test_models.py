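"""Simulator correctness against independent per-trial oracles and closed forms."""

import math

import numpy as np
import pytest

from clamplearn import models as M
from clamplearn import reference
from conftest import make_constant_schedule, make_transfer_schedule, random_schedule


# ---------------------------------------------------------------------------
# Independent, unoptimized per-trial oracles (plain python, no shared code
# with the implementation beyond the schedule container).
# ---------------------------------------------------------------------------

def oracle_state(sched, A, U, gA=1.0, gu=1.0):
    """Adaptation state recursion with optional hit-trial gains."""
    x = [0.0]
    for i in range(sched.n_trials):
        clamp = sched.block[i] == "clamp"
        if clamp and sched.hit[i] == 1:
            x.append(gA * A * x[-1] + gu * U)
        elif clamp:
            x.append(A * x[-1] + U)
        else:
            x.append(A * x[-1])
    return x[:-1]


def oracle_dual_error(sched, As, Us, At, Ut):
    xs, xt = [0.0], [0.0]
    for i in range(sched.n_trials):
        clamp = sched.block[i] == "clamp"
        spe = 1.0 if clamp else 0.0
        te = 1.0 if (clamp and sched.hit[i] == 0) else 0.0
        xs.append(As * xs[-1] + Us * spe if clamp else As * xs[-1])
        xt.append(At * xt[-1] + Ut * te if clamp else At * xt[-1])
    return xs[:-1], xt[:-1]


def oracle_population_blend(x, hits, Ap, s):
    """Population vector via literal trig sums over the reinforced directions."""
    reinforced = []  # list of (direction_deg, weight)
    ys = []
    for i, xi in enumerate(x):
        vx = sum(w * math.cos(math.radians(d)) for d, w in reinforced)
        vy = sum(w * math.sin(math.radians(d)) for d, w in reinforced)
        vl = min(math.hypot(vx, vy), 1.0)
        if vl > 0:
            vd = math.degrees(math.atan2(vy, vx))
            if vd >= 180.0:
                vd -= 360.0
            y = (1 - vl) * xi + vl * vd
        else:
            y = xi
        ys.append(y)
        reinforced = [(d, w * Ap) for d, w in reinforced]
        if hits[i] == 1:
            scaled = abs(y) * 100.0
            idx = math.floor(scaled + 0.5)
            direction = (idx if y >= 0 else -idx) / 100.0
            reinforced.append((direction, s))
    return ys


# ---------------------------------------------------------------------------
# Motor correction
# ---------------------------------------------------------------------------

class TestMotorCorrection:
    def test_terminal_matches_closed_form(self):
        sched = make_constant_schedule(1000, clamp_deg=3.5)
        traj = M.simulate_motor_correction(M.StateSpaceParams(0.9, 1.0), sched)
        assert traj.x[-1] == pytest.approx(10.0, abs=1e-6)

    def test_zero_update_stays_at_zero(self):
        sched = make_constant_schedule(50)
        traj = M.simulate_motor_correction(M.StateSpaceParams(0.9, 0.0), sched)
        assert np.all(traj.x == 0)

    def test_early_recursion_values(self):
        # x(1)=0, x(2)=1, x(3)=0.9·1+1=1.9
        sched = make_constant_schedule(3, clamp_deg=3.5)
        traj = M.simulate_motor_correction(M.StateSpaceParams(0.9, 1.0), sched)
        np.testing.assert_allclose(traj.x, [0.0, 1.0, 1.9], atol=1e-12)

    def test_parameter_domain_errors(self):
        with pytest.raises(M.ParameterDomainError):
            M.StateSpaceParams(1.5, 1.0)
        with pytest.raises(M.ParameterDomainError):
            M.StateSpaceParams(0.9, -0.2)

    def test_convergence_under_constant_regime(self):
        sched = make_constant_schedule(500)
        traj = M.simulate_motor_correction(M.StateSpaceParams(0.95, 0.5), sched)
        steps = np.abs(np.diff(traj.x))
        assert steps[-1] < 1e-8
        assert np.all(np.diff(steps[:50]) <= 1e-12)


# ---------------------------------------------------------------------------
# Movement reinforcement
# ---------------------------------------------------------------------------

class TestMovementReinforcement:
    def test_zero_increment_reduces_to_adaptation(self):
        sched = make_constant_schedule(100, hit=1)
        ss = M.StateSpaceParams(0.9, 0.3)
        traj = M.simulate_movement_reinforcement(ss, M.ReinforcementParams(0.99, 0.0), sched)
        base = M.simulate_motor_correction(ss, sched)
        np.testing.assert_allclose(traj.y, base.y, atol=1e-12)
        assert np.all(traj.v_l == 0)

    def test_all_miss_ignores_reinforcement(self):
        sched = make_constant_schedule(100, hit=0)
        ss = M.StateSpaceParams(0.9, 0.3)
        traj = M.simulate_movement_reinforcement(ss, M.ReinforcementParams(0.99, 0.8), sched)
        base = M.simulate_motor_correction(ss, sched)
        np.testing.assert_allclose(traj.y, base.y, atol=1e-12)

    def test_three_hit_trials_hand_unrolled(self):
        """Step-by-step unroll of the update rule, including V_l clipping."""
        sched = make_constant_schedule(3, hit=1, clamp_deg=3.5)
        A, U, Ap, s = 0.9, 1.0, 0.99, 0.1
        traj = M.simulate_movement_reinforcement(
            M.StateSpaceParams(A, U), M.ReinforcementParams(Ap, s), sched
        )
        x = [0.0, 1.0, 1.9]
        y = oracle_population_blend(x, [1, 1, 1], Ap, s)
        np.testing.assert_allclose(traj.y, y, atol=1e-12)
        # explicit arithmetic for trial 3: units at 0° (w=0.99·0.1) and 0.9° (w=0.1)
        vx = 0.99 * 0.1 * 1.0 + 0.1 * math.cos(math.radians(0.9))
        vy = 0.1 * math.sin(math.radians(0.9))
        vl = math.hypot(vx, vy)
        vd = math.degrees(math.atan2(vy, vx))
        assert traj.y[2] == pytest.approx((1 - vl) * 1.9 + vl * vd, abs=1e-12)

    def test_scalar_recursion_matches_dense_units(self):
        rng = np.random.default_rng(11)
        sched = random_schedule(rng, 150)
        ss = M.StateSpaceParams(0.92, 0.4)
        rp = M.ReinforcementParams(0.95, 0.2)
        fast = M.simulate_movement_reinforcement(ss, rp, sched)
        dense = reference.simulate_movement_reinforcement_dense(ss, rp, sched)
        np.testing.assert_allclose(fast.y, dense.y, atol=1e-9)
        np.testing.assert_allclose(fast.v_l, dense.v_l, atol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_no_decrease_after_miss_to_hit_transfer(self, seed):
        """The transfer signature: reinforcement cannot lower the asymptote."""
        rng = np.random.default_rng(seed)
        ss = M.StateSpaceParams(rng.uniform(0.5, 0.999), rng.uniform(0.01, 1.7))
        rp = M.ReinforcementParams(rng.uniform(0.5, 0.999), rng.uniform(0.001, 0.99))
        sched = make_transfer_schedule(800, 800)
        traj = M.simulate_movement_reinforcement(ss, rp, sched)
        pre = traj.y[700:800].mean()
        post = traj.y[-100:].mean()
        assert post >= pre - 0.1


# ---------------------------------------------------------------------------
# Adaptation modulation
# ---------------------------------------------------------------------------

class TestAdaptationModulation:
    def test_unit_gains_identity(self):
        rng = np.random.default_rng(5)
        sched = random_schedule(rng)
        base = M.StateSpaceParams(0.9, 0.5)
        mod = M.simulate_adaptation_modulation(M.ModulationParams(base, 1.0, 1.0), sched)
        mc = M.simulate_motor_correction(base, sched)
        np.testing.assert_allclose(mod.y, mc.y, atol=1e-12)

    def test_all_hit_steady_state(self):
        sched = make_constant_schedule(3000, hit=1)
        p = M.ModulationParams(M.StateSpaceParams(0.9, 1.0), 0.98, 0.5)
        traj = M.simulate_adaptation_modulation(p, sched)
        assert traj.x[-1] == pytest.approx(0.5 * 1.0 / (1 - 0.98 * 0.9), rel=1e-6)

    def test_transfer_drop_matches_closed_form(self):
        p = M.ModulationParams(M.StateSpaceParams(0.95, 0.4), 1.0, 0.5)
        sched = make_transfer_schedule(1500, 1500)
        traj = M.simulate_adaptation_modulation(p, sched)
        pre = M.steady_state("adaptation_modulation", p, "all_miss")
        post = M.steady_state("adaptation_modulation", p, "all_hit")
        assert traj.y[1499] == pytest.approx(pre, rel=1e-6)
        assert traj.y[-1] == pytest.approx(post, rel=1e-6)
        assert post < pre


# ---------------------------------------------------------------------------
# Dual error
# ---------------------------------------------------------------------------

class TestDualError:
    def test_all_hit_equals_motor_correction(self):
        sched = make_constant_schedule(200, hit=1)
        dp = M.DualErrorParams(0.9, 0.5, 0.8, 0.7)
        de = M.simulate_dual_error(dp, sched)
        mc = M.simulate_motor_correction(M.StateSpaceParams(0.9, 0.5), sched)
        np.testing.assert_allclose(de.y, mc.y, atol=1e-12)

    def test_all_miss_steady_state(self):
        sched = make_constant_schedule(3000, hit=0)
        dp = M.DualErrorParams(0.9, 0.5, 0.9, 0.5)
        traj = M.simulate_dual_error(dp, sched)
        assert traj.y[-1] == pytest.approx(10.0, rel=1e-6)

    def test_te_process_decays_geometrically_after_transfer(self):
        dp = M.DualErrorParams(0.99, 0.07, 0.95, 0.285)
        sched = make_transfer_schedule(3000, 3000)
        traj = M.simulate_dual_error(dp, sched)
        post = traj.x_te[3000:3050]
        ratios = post[1:] / post[:-1]
        np.testing.assert_allclose(ratios, 0.95, rtol=1e-6)
        assert traj.y[-1] == pytest.approx(0.07 / 0.01, rel=1e-4)


# ---------------------------------------------------------------------------
# Hybrids and steady states
# ---------------------------------------------------------------------------

class TestHybrids:
    def test_zero_increment_reduces_to_cores(self):
        rng = np.random.default_rng(9)
        sched = random_schedule(rng)
        am_core = M.ModulationParams(M.StateSpaceParams(0.9, 0.5), 0.97, 0.6)
        de_core = M.DualErrorParams(0.95, 0.3, 0.9, 0.4)
        rp0 = M.ReinforcementParams(0.9, 0.0)
        h_am = M.simulate_hybrid("mr_am", M.HybridParams(rp0, am_core), sched)
        h_de = M.simulate_hybrid("mr_de", M.HybridParams(rp0, de_core), sched)
        np.testing.assert_array_equal(h_am.y, M.simulate_adaptation_modulation(am_core, sched).y)
        np.testing.assert_array_equal(h_de.y, M.simulate_dual_error(de_core, sched).y)

    def test_unit_gains_reduce_mr_am_to_movement_reinforcement(self):
        rng = np.random.default_rng(10)
        sched = random_schedule(rng)
        ss = M.StateSpaceParams(0.9, 0.5)
        rp = M.ReinforcementParams(0.95, 0.3)
        hyb = M.simulate_hybrid(
            "mr_am", M.HybridParams(rp, M.ModulationParams(ss, 1.0, 1.0)), sched
        )
        mr = M.simulate_movement_reinforcement(ss, rp, sched)
        np.testing.assert_array_equal(hyb.y, mr.y)

    def test_core_params_are_type_checked(self):
        sched = make_constant_schedule(5)
        rp = M.ReinforcementParams(0.9, 0.1)
        wrong = M.HybridParams(rp, M.DualErrorParams(0.9, 0.1, 0.9, 0.1))
        with pytest.raises(M.ParameterDomainError):
            M.simulate_hybrid("mr_am", wrong, sched)


class TestSteadyState:
    @pytest.mark.parametrize(
        "model, params, regime, expected",
        [
            ("motor_correction", M.StateSpaceParams(0.9, 1.0), "all_miss", 10.0),
            ("dual_error", M.DualErrorParams(0.9, 0.5, 0.9, 0.5), "all_miss", 10.0),
            ("dual_error", M.DualErrorParams(0.9, 0.5, 0.9, 0.5), "all_hit", 5.0),
            (
                "adaptation_modulation",
                M.ModulationParams(M.StateSpaceParams(0.9, 1.0), 1.0, 0.5),
                "all_hit",
                5.0,
            ),
        ],
    )
    def test_closed_forms(self, model, params, regime, expected):
        assert M.steady_state(model, params, regime) == pytest.approx(expected)

    def test_reinforcement_all_hit_unsupported(self):
        with pytest.raises(M.UnsupportedRegimeError):
            M.steady_state(
                "movement_reinforcement",
                (M.StateSpaceParams(0.9, 1.0), M.ReinforcementParams(0.9, 0.1)),
                "all_hit",
            )


# ---------------------------------------------------------------------------
# Oracle cross-checks on random schedules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_all_simulators_match_per_trial_oracles(seed):
    rng = np.random.default_rng(seed)
    sched = random_schedule(rng, 200)
    A, U = rng.uniform(0.6, 0.99), rng.uniform(0.05, 1.5)
    gA, gu = rng.uniform(0.5, 1.5), rng.uniform(0.1, 1.5)
    Ap, s = rng.uniform(0.7, 0.99), rng.uniform(0.01, 0.5)

    mc = M.simulate_motor_correction(M.StateSpaceParams(A, U), sched)
    np.testing.assert_allclose(mc.x, oracle_state(sched, A, U), atol=1e-9)

    am = M.simulate_adaptation_modulation(
        M.ModulationParams(M.StateSpaceParams(A, U), gA, gu), sched
    )
    np.testing.assert_allclose(am.x, oracle_state(sched, A, U, gA, gu), atol=1e-9)

    de = M.simulate_dual_error(M.DualErrorParams(A, U, gA * 0.6, gu * 0.5), sched)
    xs, xt = oracle_dual_error(sched, A, U, gA * 0.6, gu * 0.5)
    np.testing.assert_allclose(de.x_spe, xs, atol=1e-9)
    np.testing.assert_allclose(de.x_te, xt, atol=1e-9)

    mr = M.simulate_movement_reinforcement(
        M.StateSpaceParams(A, U), M.ReinforcementParams(Ap, s), sched
    )
    y_oracle = oracle_population_blend(oracle_state(sched, A, U), sched.hit, Ap, s)
    np.testing.assert_allclose(mr.y, y_oracle, atol=1e-9)

    hyb = M.simulate_hybrid(
        "mr_de",
        M.HybridParams(M.ReinforcementParams(Ap, s), M.DualErrorParams(A, U, 0.9, 0.3)),
        sched,
    )
    xs, xt = oracle_dual_error(sched, A, U, 0.9, 0.3)
    total = [a + b for a, b in zip(xs, xt)]
    np.testing.assert_allclose(
        hyb.y, oracle_population_blend(total, sched.hit, Ap, s), atol=1e-9
    )


def test_trajectory_frame_round_trip(tmp_path):
    sched = make_constant_schedule(10, hit=1)
    traj = M.simulate_dual_error(M.DualErrorParams(0.9, 0.5, 0.9, 0.2), sched)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert set(df.columns) >= {"trial", "cycle", "x", "y", "x_spe", "x_te"}
    np.testing.assert_allclose(df["y"], traj.y)
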