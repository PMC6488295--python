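"""Dense population-vector bookkeeping for the reinforcement process.

The production simulators in :mod:`clamplearn.models` exploit the linearity
of the population vector in the unit weights and track only its x/y
components.  This module keeps the full weight vector over all 36,000
directionally tuned units (0.01° resolution) explicit.  It is the slower,
literal form of the same process — useful for inspecting the weight
distribution and for cross-checking the scalar recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import (
    N_UNITS,
    ReinforcementParams,
    StateSpaceParams,
    Trajectory,
    _core_motor_correction,
)
from .paradigm import ClampSchedule

__all__ = ["ReinforcementState", "simulate_movement_reinforcement_dense"]


def _unit_angles_deg() -> np.ndarray:
    return np.arange(N_UNITS) * 0.01


@dataclass
class ReinforcementState:
    """Weights over the tuned-unit population and the derived vector.

    ``r[i]`` is the non-negative weight of the unit preferring direction
    ``i·0.01°``.  The population vector has components
    ``Vx = r·cos(u)``, ``Vy = r·sin(u)``; its direction ``V_d`` (degrees in
    [−180, 180)) is the mean preferred direction and its length ``V_l`` is
    clipped to [0, 1] to act as a convex blending weight.
    """

    r: np.ndarray = field(default_factory=lambda: np.zeros(N_UNITS))

    def __post_init__(self) -> None:
        if self.r.shape != (N_UNITS,):
            raise ValueError(f"weight vector must have length {N_UNITS}")
        if np.any(self.r < 0):
            raise ValueError("unit weights must be non-negative")

    @property
    def unit_angles_deg(self) -> np.ndarray:
        return _unit_angles_deg()

    def population_vector(self) -> tuple[float, float, float, float]:
        """Return (Vx, Vy, V_d degrees, V_l clipped)."""
        ang = np.radians(self.unit_angles_deg)
        vx = float(self.r @ np.cos(ang))
        vy = float(self.r @ np.sin(ang))
        vl = min(math.hypot(vx, vy), 1.0)
        vd = math.degrees(math.atan2(vy, vx)) if vl > 0 else 0.0
        if vd >= 180.0:
            vd -= 360.0
        return vx, vy, vd, vl

    @staticmethod
    def unit_index(direction_deg: float) -> int:
        """Index of the unit at the 0.01°-rounded direction (ties away from 0)."""
        scaled = abs(direction_deg) * 100.0
        idx = int(math.floor(scaled + 0.5))
        if direction_deg < 0:
            idx = -idx
        return idx % N_UNITS

    def update(self, direction_deg: float, hit: bool, p: ReinforcementParams) -> None:
        """Decay all weights by A'; add s at the executed direction on a hit."""
        self.r *= p.A_prime
        if hit:
            self.r[self.unit_index(direction_deg)] += p.s


def simulate_movement_reinforcement_dense(
    ss: StateSpaceParams, rp: ReinforcementParams, sched: ClampSchedule
) -> Trajectory:
    """Literal per-unit form of the movement-reinforcement simulator."""
    err = sched.is_clamp.astype(float)
    hit = sched.hit.astype(int)
    x = _core_motor_correction(err, ss.A, ss.U)
    state = ReinforcementState()
    n = sched.n_trials
    y = np.zeros(n)
    v_l = np.zeros(n)
    v_d = np.zeros(n)
    for i in range(n):
        _, _, vd, vl = state.population_vector()
        y[i] = (1.0 - vl) * x[i] + vl * vd if vl > 0 else x[i]
        v_l[i] = vl
        v_d[i] = vd if vl > 0 else 0.0
        state.update(y[i], hit[i] == 1, rp)
    return Trajectory(x=x, y=y, v_l=v_l, v_d=v_d, schedule=sched)
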