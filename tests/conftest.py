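import numpy as np
import pytest

from clamplearn import paradigm as P
from clamplearn import synth as S


def make_constant_schedule(n_trials: int, hit: int = 0, clamp_deg: float = 1.75,
                           block: str = "clamp") -> P.ClampSchedule:
    """Single-target schedule of identical trials (one trial per cycle)."""
    return P.ClampSchedule(
        block=np.full(n_trials, block, dtype=object),
        clamp_deg=np.full(n_trials, clamp_deg if block == "clamp" else 0.0),
        hit=np.full(n_trials, hit, dtype=int),
        target_deg=np.zeros(n_trials),
        cycle=np.arange(1, n_trials + 1),
        targets=(0.0,),
    )


def make_transfer_schedule(n1: int, n2: int, hit1: int = 0, hit2: int = 1,
                           clamp_deg: float = 1.75) -> P.ClampSchedule:
    """Two-phase all-clamp schedule (e.g. miss→hit), one trial per cycle."""
    n = n1 + n2
    return P.ClampSchedule(
        block=np.full(n, "clamp", dtype=object),
        clamp_deg=np.full(n, clamp_deg),
        hit=np.concatenate([np.full(n1, hit1), np.full(n2, hit2)]).astype(int),
        target_deg=np.zeros(n),
        cycle=np.arange(1, n + 1),
        targets=(0.0,),
    )


def random_schedule(rng: np.random.Generator, n_trials: int = 200) -> P.ClampSchedule:
    """Random mix of block types and outcomes for oracle cross-checks."""
    blocks = rng.choice(
        ["baseline_nofb", "baseline_veridical", "clamp", "zero_clamp", "washout_nofb"],
        size=n_trials,
        p=[0.1, 0.1, 0.6, 0.1, 0.1],
    )
    hit = (rng.random(n_trials) < 0.5).astype(int)
    hit[blocks != "clamp"] = 0
    return P.ClampSchedule(
        block=blocks.astype(object),
        clamp_deg=np.where(blocks == "clamp", 1.75, 0.0),
        hit=hit,
        target_deg=np.zeros(n_trials),
        cycle=np.arange(1, n_trials + 1),
        targets=(0.0,),
    )


@pytest.fixture(scope="session")
def exp3_schedules():
    return {
        "s2h": P.build_design("exp3_straddle_to_hit", seed=0),
        "h2s": P.build_design("exp3_hit_to_straddle", seed=0),
    }


@pytest.fixture(scope="session")
def exp3_dataset(exp3_schedules):
    """Two-group synthetic transfer experiment at the default study conditions."""
    cfgs = [
        S.GeneratorConfig(design=exp3_schedules["s2h"]),
        S.GeneratorConfig(design=exp3_schedules["h2s"]),
    ]
    data, truth = S.generate_experiment(cfgs, ["s2h", "h2s"], seed=20260927)
    return data, truth
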