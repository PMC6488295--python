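"""Geometry and block structure of clamped-feedback reaching experiments.

In the error-clamp paradigm the cursor travels along a fixed angular path
relative to the target, independent of the hand.  Whether the clamped cursor
ends up fully inside the target (a "hit"), partially overlapping it
("straddle"), or fully outside it ("miss") is a pure function of the clamp
angle and the cursor/target geometry; the experiments manipulate task outcome
by varying target size while holding the clamp angle — and therefore the
sensory prediction error — constant.

This module encodes that geometry (:func:`classify_task_outcome`) and the
trial-by-trial block structure of the three experiments
(:func:`build_design`), producing the :class:`ClampSchedule` every simulator
and the preprocessing pipeline consume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Geometry",
    "TaskOutcome",
    "Block",
    "Phase",
    "ClampSchedule",
    "classify_task_outcome",
    "center_distance",
    "build_design",
    "EXP1_TARGETS",
    "EXP2_TARGETS",
]

#: Target locations (deg) for the 8-target designs, 45° apart.
EXP1_TARGETS: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
#: Target locations (deg) for the 4-target design, 90° apart.
EXP2_TARGETS: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)


class TaskOutcome(str, Enum):
    """Geometric relation of the clamped cursor endpoint to the target."""

    hit = "hit"
    straddle = "straddle"
    miss = "miss"


class Block(str, Enum):
    """Within-session block types."""

    baseline_nofb = "baseline_nofb"
    baseline_veridical = "baseline_veridical"
    clamp = "clamp"
    zero_clamp = "zero_clamp"
    washout_nofb = "washout_nofb"
    washout_veridical = "washout_veridical"


class InvalidGeometryError(ValueError):
    """Raised when a Geometry has non-positive dimensions or clamp ≥ 90°."""


@dataclass(frozen=True)
class Geometry:
    """Endpoint geometry of one clamp condition.

    Parameters
    ----------
    clamp_angle
        Angular offset of the clamped cursor path from the target, degrees.
    target_diameter, cursor_diameter
        Diameters in mm.
    radial_distance
        Distance from start position to target center, mm (8 cm in the
        experiments modeled here).
    """

    clamp_angle: float
    target_diameter: float
    cursor_diameter: float
    radial_distance: float = 80.0

    def __post_init__(self) -> None:
        if (
            self.target_diameter <= 0
            or self.cursor_diameter <= 0
            or self.radial_distance <= 0
        ):
            raise InvalidGeometryError(
                "target, cursor and radial distance must be strictly positive"
            )
        if not 0 <= self.clamp_angle < 90:
            raise InvalidGeometryError("clamp angle must lie in [0, 90) degrees")


def center_distance(g: Geometry) -> float:
    """Euclidean distance (mm) between cursor and target centers.

    Both endpoints lie on the circle of radius ``radial_distance``; the
    distance is the chord length ``2 R sin(e/2)`` for clamp angle ``e``.
    """
    return 2.0 * g.radial_distance * math.sin(math.radians(g.clamp_angle) / 2.0)


def classify_task_outcome(g: Geometry) -> tuple[TaskOutcome, float]:
    """Classify the clamp endpoint as hit/straddle/miss.

    Returns the outcome and the cursor-to-target center distance in mm.  The
    cursor is a *hit* when fully embedded in the target
    (``d + r_cursor <= r_target``), a *miss* when fully outside
    (``d - r_cursor >= r_target``), and a *straddle* otherwise.  Boundary
    contact counts toward the embedded side, making the partition closed.
    """
    d = center_distance(g)
    r_t = g.target_diameter / 2.0
    r_c = g.cursor_diameter / 2.0
    if d + r_c <= r_t:
        return TaskOutcome.hit, d
    if d - r_c >= r_t:
        return TaskOutcome.miss, d
    return TaskOutcome.straddle, d


@dataclass(frozen=True)
class Phase:
    """One contiguous block of cycles with a constant feedback condition."""

    n_cycles: int
    block: Block
    clamp_deg: float = 0.0
    hit: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise ValueError("phase cycle count must be non-negative")


@dataclass
class ClampSchedule:
    """Per-trial design of one session.

    All arrays have length ``n_trials``.  ``clamp_deg`` is the clamp size
    (0 in non-clamp blocks; it equals the constant sensory prediction error
    magnitude during clamp blocks).  ``hit`` is 1 when the clamped cursor
    lands fully inside the target; target error is ``1 - hit`` (1 on miss
    *and* straddle).  ``cycle`` is 1-based and visits each target exactly
    once per cycle.
    """

    block: np.ndarray  # dtype object/str of Block values
    clamp_deg: np.ndarray  # float degrees
    hit: np.ndarray  # int {0, 1}
    target_deg: np.ndarray  # float degrees
    cycle: np.ndarray  # int, 1-based
    targets: tuple[float, ...] = field(default=EXP1_TARGETS)

    @property
    def n_trials(self) -> int:
        return len(self.cycle)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def is_clamp(self) -> np.ndarray:
        """Boolean mask of clamp-block trials (error term present)."""
        return self.block == Block.clamp.value

    def validate(self) -> None:
        n = self.n_trials
        arrays = (self.block, self.clamp_deg, self.hit, self.target_deg, self.cycle)
        if any(len(a) != n for a in arrays):
            raise ValueError("schedule arrays must share one length")
        if n and np.any(np.diff(self.cycle) < 0):
            raise ValueError("cycle index must be non-decreasing")
        for c in np.unique(self.cycle):
            targs = np.sort(self.target_deg[self.cycle == c])
            if not np.array_equal(targs, np.sort(np.asarray(self.targets))):
                raise ValueError(
                    f"cycle {c} does not visit each target exactly once"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "cycle": self.cycle,
                "block": self.block,
                "target_deg": self.target_deg,
                "clamp_deg": self.clamp_deg,
                "hit": self.hit,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, targets: Sequence[float] | None = None) -> "ClampSchedule":
        if targets is None:
            targets = tuple(sorted(df["target_deg"].unique()))
        return cls(
            block=df["block"].to_numpy(dtype=object),
            clamp_deg=df["clamp_deg"].to_numpy(dtype=float),
            hit=df["hit"].to_numpy(dtype=int),
            target_deg=df["target_deg"].to_numpy(dtype=float),
            cycle=df["cycle"].to_numpy(dtype=int),
            targets=tuple(targets),
        )

    @classmethod
    def from_csv(cls, path) -> "ClampSchedule":
        return cls.from_frame(pd.read_csv(path))

    def clamp_cycles(self) -> np.ndarray:
        """Sorted unique cycle indices belonging to clamp blocks."""
        return np.unique(self.cycle[self.is_clamp])


def _phases_to_schedule(
    phases: Iterable[Phase],
    targets: Sequence[float],
    seed: int | None = 0,
) -> ClampSchedule:
    rng = np.random.default_rng(seed)
    targets = tuple(targets)
    k = len(targets)
    block_col: list[str] = []
    clamp_col: list[float] = []
    hit_col: list[int] = []
    target_col: list[float] = []
    cycle_col: list[int] = []
    cycle_no = 0
    for ph in phases:
        for _ in range(ph.n_cycles):
            cycle_no += 1
            order = rng.permutation(k)
            for j in order:
                block_col.append(ph.block.value)
                clamp_col.append(ph.clamp_deg)
                hit_col.append(int(ph.hit))
                target_col.append(targets[j])
                cycle_col.append(cycle_no)
    return ClampSchedule(
        block=np.asarray(block_col, dtype=object),
        clamp_deg=np.asarray(clamp_col, dtype=float),
        hit=np.asarray(hit_col, dtype=int),
        target_deg=np.asarray(target_col, dtype=float),
        cycle=np.asarray(cycle_col, dtype=int),
        targets=targets,
    )


#: Target diameters (mm) producing hit / straddle / miss at a 3.5° clamp.
EXP1_TARGET_DIAMETERS = {"hit": 16.0, "straddle": 9.8, "miss": 6.0}

_OUTCOME_HIT = {"hit": 1, "straddle": 0, "miss": 0}


def build_design(
    experiment: str,
    outcome: str = "miss",
    phases: Sequence[Phase] | None = None,
    targets: Sequence[float] | None = None,
    seed: int | None = 0,
) -> ClampSchedule:
    """Build the per-trial schedule of a named or custom experiment.

    Parameters
    ----------
    experiment
        One of ``exp1``, ``exp2``, ``exp3_straddle_to_hit``,
        ``exp3_hit_to_straddle``, ``exp3_control``, or ``custom``.
    outcome
        Task outcome of the clamp block for ``exp1``/``exp2``
        (``hit``/``straddle``/``miss``); ignored for the exp3 designs whose
        outcome sequence is fixed by name.  The exp3 control group trains
        with the bisected large target, represented as hit throughout.
    phases
        For ``custom``: explicit list of :class:`Phase`.
    targets
        Target locations; defaults to the named design's set.
    seed
        Seeds the within-cycle target permutation (ordering is not analyzed;
        every cycle still visits each target once).

    Named designs (cycle counts):

    - ``exp1``: 5 no-feedback + 10 veridical baseline, 80 clamp (3.5°),
      5 no-feedback + 10 veridical washout; 8 targets.
    - ``exp2``: 10 no-feedback + 10 veridical baseline, 220 clamp (1.75°),
      10 zero-clamp + 10 veridical washout; 4 targets.
    - ``exp3_*``: 5 + 5 baseline, 120 clamp (acquisition outcome) + 80 clamp
      (transfer outcome), both 1.75°; 8 targets; no washout.
    """
    if experiment == "custom":
        if phases is None:
            raise ValueError("custom design requires a phase list")
        return _phases_to_schedule(phases, targets or EXP1_TARGETS, seed)

    if experiment == "exp1":
        if outcome not in _OUTCOME_HIT:
            raise ValueError(f"unknown outcome {outcome!r}")
        hit = _OUTCOME_HIT[outcome]
        ph = [
            Phase(5, Block.baseline_nofb),
            Phase(10, Block.baseline_veridical),
            Phase(80, Block.clamp, 3.5, hit),
            Phase(5, Block.washout_nofb),
            Phase(10, Block.washout_veridical),
        ]
        return _phases_to_schedule(ph, targets or EXP1_TARGETS, seed)

    if experiment == "exp2":
        if outcome not in _OUTCOME_HIT:
            raise ValueError(f"unknown outcome {outcome!r}")
        hit = _OUTCOME_HIT[outcome]
        ph = [
            Phase(10, Block.baseline_nofb),
            Phase(10, Block.baseline_veridical),
            Phase(220, Block.clamp, 1.75, hit),
            Phase(10, Block.zero_clamp, 0.0, 1),
            Phase(10, Block.washout_veridical),
        ]
        return _phases_to_schedule(ph, targets or EXP2_TARGETS, seed)

    exp3_outcomes = {
        "exp3_straddle_to_hit": (0, 1),
        "exp3_hit_to_straddle": (1, 0),
        "exp3_control": (1, 1),
    }
    if experiment in exp3_outcomes:
        h1, h2 = exp3_outcomes[experiment]
        ph = [
            Phase(5, Block.baseline_nofb),
            Phase(5, Block.baseline_veridical),
            Phase(120, Block.clamp, 1.75, h1),
            Phase(80, Block.clamp, 1.75, h2),
        ]
        return _phases_to_schedule(ph, targets or EXP1_TARGETS, seed)

    raise ValueError(f"unknown experiment id {experiment!r}")


def design_spec_to_json(phases: Sequence[Phase], targets: Sequence[float]) -> str:
    """Serialize a custom design spec as JSON."""
    return json.dumps(
        {
            "targets": list(targets),
            "phases": [
                {
                    "n_cycles": p.n_cycles,
                    "block": p.block.value,
                    "clamp_deg": p.clamp_deg,
                    "hit": p.hit,
                }
                for p in phases
            ],
        },
        indent=2,
    )


def design_spec_from_json(text: str) -> tuple[list[Phase], tuple[float, ...]]:
    """Parse a JSON design spec back into phases + targets."""
    obj = json.loads(text)
    phases = [
        Phase(p["n_cycles"], Block(p["block"]), p.get("clamp_deg", 0.0), p.get("hit", 0))
        for p in obj["phases"]
    ]
    return phases, tuple(obj["targets"])
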