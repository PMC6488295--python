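"""Trial-by-trial models of implicit adaptation under clamped feedback.

Five generative accounts of how task outcome (hitting vs. missing the
target) shapes implicit sensorimotor adaptation, all built on a single-rate
state-space recursion in hand-angle space:

* **Motor correction** (baseline): ``x(n+1) = A·x(n) + U`` on clamp trials.
  Because the clamp fixes the error size ``e``, the update ``U(e)`` is a
  single free parameter; ``A`` is trial-to-trial retention.
* **Movement reinforcement**: adaptation is outcome-blind, but a model-free
  operant process — a population vector over 36,000 directionally tuned
  units at 0.01° resolution — reinforces the executed direction on hit
  trials and biases the motor output toward previously rewarded movements:
  ``y = (1 − V_l)·x + V_l·V_d``.
* **Adaptation modulation**: task success directly gates adaptation,
  scaling retention and update by gains γ_A, γ_u on hit trials.
* **Dual error**: two parallel implicit processes, one driven by the sensory
  prediction error (present on every clamp trial) and one driven by the
  binary target error (present only on miss/straddle trials); the motor
  output is their sum.
* **Hybrids** (``mr_am``, ``mr_de``): the population-vector process layered
  on top of the modulated or dual-error adaptation state.

Sign convention: positive hand angle is the direction opposite the clamp
(the direction adaptation drives the hand).  All states start at zero and
all reinforcement weights start at zero, matching baseline-subtracted data.

The per-trial recursions are compiled with numba.  For the reinforcement
models the population vector is linear in the unit weights, so its x/y
components obey exact scalar recursions (decay by A′ every trial, increment
by ``s·(cos θ, sin θ)`` on hit trials); a dense 36,000-unit reference
implementation lives in :mod:`clamplearn.reference`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit

from .paradigm import ClampSchedule

__all__ = [
    "StateSpaceParams",
    "ReinforcementParams",
    "ModulationParams",
    "DualErrorParams",
    "HybridParams",
    "Trajectory",
    "simulate_motor_correction",
    "simulate_movement_reinforcement",
    "simulate_adaptation_modulation",
    "simulate_dual_error",
    "simulate_hybrid",
    "simulate",
    "steady_state",
    "cycle_means",
    "MODEL_IDS",
    "N_UNITS",
    "UNIT_RESOLUTION_DEG",
]

#: Directionally tuned units in the reinforcement population, at 0.01°.
N_UNITS = 36_000
UNIT_RESOLUTION_DEG = 0.01

#: Guard against divergent parameter regions explored during fitting.
_STATE_CAP = 1.0e6

MODEL_IDS = (
    "motor_correction",
    "movement_reinforcement",
    "adaptation_modulation",
    "dual_error",
    "mr_am",
    "mr_de",
)


class ParameterDomainError(ValueError):
    """Raised when model parameters violate their domain constraints."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterDomainError(msg)


@dataclass(frozen=True)
class StateSpaceParams:
    """Retention ``A`` (unitless, 0<A<1) and update ``U`` (deg/trial, ≥0)."""

    A: float
    U: float

    def __post_init__(self) -> None:
        _check(0.0 < self.A < 1.0, "retention A must lie in (0, 1)")
        _check(self.U >= 0.0, "update U must be non-negative")


@dataclass(frozen=True)
class ReinforcementParams:
    """Weight retention ``A'`` (0<A'<1) and reinforcement increment ``s`` (≥0)."""

    A_prime: float
    s: float

    def __post_init__(self) -> None:
        _check(0.0 < self.A_prime < 1.0, "weight retention A' must lie in (0, 1)")
        _check(self.s >= 0.0, "reinforcement increment s must be non-negative")


@dataclass(frozen=True)
class ModulationParams:
    """State-space core plus hit-trial gains on retention and update.

    Gains apply only on hit trials (they are 1 on miss trials by
    construction); they are unconstrained above zero, so success may either
    amplify or attenuate retention/updating.
    """

    base: StateSpaceParams
    gamma_A: float
    gamma_u: float

    def __post_init__(self) -> None:
        _check(self.gamma_A > 0 and self.gamma_u > 0, "gains must be strictly positive")


@dataclass(frozen=True)
class DualErrorParams:
    """Retention/update pairs for the SPE-driven and TE-driven processes."""

    A_spe: float
    U_spe: float
    A_te: float
    U_te: float

    def __post_init__(self) -> None:
        _check(0.0 < self.A_spe < 1.0, "A_spe must lie in (0, 1)")
        _check(0.0 < self.A_te < 1.0, "A_te must lie in (0, 1)")
        _check(self.U_spe >= 0.0 and self.U_te >= 0.0, "updates must be non-negative")


@dataclass(frozen=True)
class HybridParams:
    """Reinforcement pair plus the core (modulation or dual-error) parameters."""

    reinforcement: ReinforcementParams
    core: ModulationParams | DualErrorParams


@dataclass
class Trajectory:
    """Per-trial model states and expected motor output (degrees).

    ``x`` is the adaptation state used on each trial (``x[0] = 0``);
    ``y`` the expected hand angle.  Component states are populated where the
    model defines them.
    """

    x: np.ndarray
    y: np.ndarray
    x_spe: np.ndarray | None = None
    x_te: np.ndarray | None = None
    v_l: np.ndarray | None = None
    v_d: np.ndarray | None = None
    schedule: ClampSchedule | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        data = {"x": self.x, "y": self.y}
        if self.schedule is not None:
            data = {
                "trial": np.arange(1, len(self.y) + 1),
                "cycle": self.schedule.cycle,
                **data,
            }
        for name in ("x_spe", "x_te", "v_l", "v_d"):
            val = getattr(self, name)
            if val is not None:
                data[name] = val
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def cycle_means(y: np.ndarray, sched: ClampSchedule, clamp_only: bool = True) -> np.ndarray:
    """Mean of per-trial output within each cycle (clamp cycles by default)."""
    mask = sched.is_clamp if clamp_only else np.ones(sched.n_trials, bool)
    cyc = sched.cycle[mask]
    vals = y[mask]
    order = np.unique(cyc)
    sums = np.zeros(order.size)
    counts = np.zeros(order.size)
    idx = np.searchsorted(order, cyc)
    np.add.at(sums, idx, vals)
    np.add.at(counts, idx, 1)
    return sums / counts


def _schedule_arrays(sched: ClampSchedule) -> tuple[np.ndarray, np.ndarray]:
    err = sched.is_clamp.astype(np.float64)
    hit = sched.hit.astype(np.int64)
    return err, hit


@njit(cache=True)
def _core_motor_correction(err, A, U):  # pragma: no cover - compiled
    n = err.shape[0]
    x = np.zeros(n)
    cur = 0.0
    for i in range(n):
        x[i] = cur
        cur = A * cur + U * err[i]
        if cur > _STATE_CAP:
            cur = _STATE_CAP
        elif cur < -_STATE_CAP:
            cur = -_STATE_CAP
    return x


@njit(cache=True)
def _core_modulation(err, hit, A, U, gA, gu):  # pragma: no cover - compiled
    n = err.shape[0]
    x = np.zeros(n)
    cur = 0.0
    for i in range(n):
        x[i] = cur
        if err[i] > 0.0 and hit[i] == 1:
            cur = gA * A * cur + gu * U
        else:
            cur = A * cur + U * err[i]
        if cur > _STATE_CAP:
            cur = _STATE_CAP
        elif cur < -_STATE_CAP:
            cur = -_STATE_CAP
    return x


@njit(cache=True)
def _core_dual_error(err, hit, As, Us, At, Ut):  # pragma: no cover - compiled
    n = err.shape[0]
    xs = np.zeros(n)
    xt = np.zeros(n)
    cs = 0.0
    ct = 0.0
    for i in range(n):
        xs[i] = cs
        xt[i] = ct
        te = err[i] * (1.0 - hit[i])
        cs = As * cs + Us * err[i]
        ct = At * ct + Ut * te
        if cs > _STATE_CAP:
            cs = _STATE_CAP
        if ct > _STATE_CAP:
            ct = _STATE_CAP
    return xs, xt


@njit(cache=True)
def _round_unit_deg(y):  # pragma: no cover - compiled
    # nearest 0.01° unit, ties rounding half away from zero
    if y >= 0.0:
        return math.floor(y * 100.0 + 0.5) / 100.0
    return -math.floor(-y * 100.0 + 0.5) / 100.0


@njit(cache=True)
def _blend_population_vector(x, hit, Ap, s):  # pragma: no cover - compiled
    """Combine an adaptation state with the population-vector process.

    Exact scalar form of the 36,000-unit population vector: V's components
    decay by A' every trial and gain s·(cos θ, sin θ) at the reinforced
    0.01°-rounded direction θ of the executed movement on hit trials.
    """
    n = x.shape[0]
    y = np.zeros(n)
    v_l = np.zeros(n)
    v_d = np.zeros(n)
    vx = 0.0
    vy = 0.0
    for i in range(n):
        vl = math.sqrt(vx * vx + vy * vy)
        if vl > 1.0:
            vl = 1.0
        if vl > 0.0:
            vd = math.degrees(math.atan2(vy, vx))
            if vd >= 180.0:
                vd -= 360.0
            y[i] = (1.0 - vl) * x[i] + vl * vd
            v_d[i] = vd
        else:
            y[i] = x[i]
        v_l[i] = vl
        vx *= Ap
        vy *= Ap
        if hit[i] == 1:
            theta = math.radians(_round_unit_deg(y[i]))
            vx += s * math.cos(theta)
            vy += s * math.sin(theta)
    return y, v_l, v_d


def simulate_motor_correction(p: StateSpaceParams, sched: ClampSchedule) -> Trajectory:
    """Baseline single-rate state space: retention + fixed update on clamp trials.

    Non-clamp trials (no feedback, veridical baseline, zero-clamp washout)
    evolve by retention only.  ``y = x``.
    """
    _require_trials(sched)
    err, _ = _schedule_arrays(sched)
    x = _core_motor_correction(err, p.A, p.U)
    return Trajectory(x=x, y=x.copy(), schedule=sched)


def simulate_movement_reinforcement(
    ss: StateSpaceParams, rp: ReinforcementParams, sched: ClampSchedule
) -> Trajectory:
    """Outcome-blind adaptation plus operant reinforcement of hit directions.

    The adaptation state evolves exactly as in the motor-correction model.
    The motor output blends it with the population-vector direction,
    weighted by the vector length clipped to [0, 1]; when all weights are
    zero the direction is undefined and the output falls back to ``x``.
    """
    _require_trials(sched)
    err, hit = _schedule_arrays(sched)
    x = _core_motor_correction(err, ss.A, ss.U)
    y, v_l, v_d = _blend_population_vector(x, hit, rp.A_prime, rp.s)
    return Trajectory(x=x, y=y, v_l=v_l, v_d=v_d, schedule=sched)


def simulate_adaptation_modulation(mp: ModulationParams, sched: ClampSchedule) -> Trajectory:
    """Success gates adaptation: hit trials use γ_A·A and γ_u·U; ``y = x``."""
    _require_trials(sched)
    err, hit = _schedule_arrays(sched)
    x = _core_modulation(err, hit, mp.base.A, mp.base.U, mp.gamma_A, mp.gamma_u)
    return Trajectory(x=x, y=x.copy(), schedule=sched)


def simulate_dual_error(dp: DualErrorParams, sched: ClampSchedule) -> Trajectory:
    """Sum of an SPE-driven and a TE-driven implicit process.

    The SPE process updates on every clamp trial; the TE process updates
    only on clamp trials whose outcome is a miss or straddle (TE = 1 − hit).
    """
    _require_trials(sched)
    err, hit = _schedule_arrays(sched)
    xs, xt = _core_dual_error(err, hit, dp.A_spe, dp.U_spe, dp.A_te, dp.U_te)
    total = xs + xt
    return Trajectory(x=total, y=total.copy(), x_spe=xs, x_te=xt, schedule=sched)


def simulate_hybrid(variant: Literal["mr_am", "mr_de"], params: HybridParams,
                    sched: ClampSchedule) -> Trajectory:
    """Population-vector reinforcement over a modulated or dual-error core."""
    _require_trials(sched)
    err, hit = _schedule_arrays(sched)
    if variant == "mr_am":
        core = params.core
        if not isinstance(core, ModulationParams):
            raise ParameterDomainError("mr_am hybrid requires ModulationParams core")
        x = _core_modulation(err, hit, core.base.A, core.base.U, core.gamma_A, core.gamma_u)
        xs = xt = None
    elif variant == "mr_de":
        core = params.core
        if not isinstance(core, DualErrorParams):
            raise ParameterDomainError("mr_de hybrid requires DualErrorParams core")
        xs, xt = _core_dual_error(err, hit, core.A_spe, core.U_spe, core.A_te, core.U_te)
        x = xs + xt
    else:
        raise ValueError(f"unknown hybrid variant {variant!r}")
    rp = params.reinforcement
    y, v_l, v_d = _blend_population_vector(x, hit, rp.A_prime, rp.s)
    return Trajectory(x=x, y=y, x_spe=xs, x_te=xt, v_l=v_l, v_d=v_d, schedule=sched)


def simulate(model: str, params, sched: ClampSchedule) -> Trajectory:
    """Dispatch on model id (see :data:`MODEL_IDS`)."""
    if model == "motor_correction":
        return simulate_motor_correction(params, sched)
    if model == "movement_reinforcement":
        return simulate_movement_reinforcement(params[0], params[1], sched) \
            if isinstance(params, tuple) else simulate_movement_reinforcement(
                StateSpaceParams(params.core.A, params.core.U), params.reinforcement, sched)
    if model == "adaptation_modulation":
        return simulate_adaptation_modulation(params, sched)
    if model == "dual_error":
        return simulate_dual_error(params, sched)
    if model in ("mr_am", "mr_de"):
        return simulate_hybrid(model, params, sched)
    raise ValueError(f"unknown model id {model!r}")


class UnsupportedRegimeError(ValueError):
    """Raised when a closed-form steady state does not exist."""


def steady_state(model: str, params, outcome_regime: Literal["all_hit", "all_miss"]) -> float:
    """Closed-form fixed point of the clamp-trial recursion (degrees).

    The movement-reinforcement output under all-hit has no schedule-free
    fixed point (the population vector depends on reinforcement history),
    so that regime raises :class:`UnsupportedRegimeError`.
    """
    if model == "motor_correction":
        return params.U / (1.0 - params.A)
    if model == "adaptation_modulation":
        if outcome_regime == "all_hit":
            denom = 1.0 - params.gamma_A * params.base.A
            if denom <= 0:
                raise UnsupportedRegimeError("retention product must be < 1")
            return params.gamma_u * params.base.U / denom
        return params.base.U / (1.0 - params.base.A)
    if model == "dual_error":
        spe = params.U_spe / (1.0 - params.A_spe)
        if outcome_regime == "all_hit":
            return spe
        return spe + params.U_te / (1.0 - params.A_te)
    if model == "movement_reinforcement":
        if outcome_regime == "all_hit":
            raise UnsupportedRegimeError(
                "movement-reinforcement all-hit asymptote depends on schedule history"
            )
        ss = params[0] if isinstance(params, tuple) else params
        return ss.U / (1.0 - ss.A)
    raise ValueError(f"unknown model id {model!r}")


def params_to_json(params) -> str:
    """Serialize any parameter bundle as JSON."""
    return json.dumps(asdict(params), indent=2)


def _require_trials(sched: ClampSchedule) -> None:
    if sched.n_trials < 1:
        raise ValueError("schedule must contain at least one trial")
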