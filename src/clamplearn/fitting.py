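"""Model fitting, comparison, and bootstrap confidence intervals.

Models are fit to cycle-level learning functions (clamp-phase cycle means),
optionally for two groups simultaneously with one shared parameter set —
the natural design for transfer experiments where one parameterization must
explain both groups' schedules.  The objective is the summed squared error
between observed and simulated cycle means; optimization is bounded local
search (scipy Powell) restarted from ``n_starts`` seeded uniform-random
interior points, mirroring the usual fmincon-with-restarts recipe.

Goodness of fit: ``R² = 1 − SSE/SST`` with SST about the pooled observed
mean, and the least-squares Gaussian AIC ``N·ln(SSE/N) + 2k`` where ``N``
counts fitted cycle means and ``k`` free parameters.  Parameter CIs come
from a participant-resampling bootstrap: resample participants with
replacement within each group, rebuild the group-averaged cycle series,
refit, and take percentile intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import models as M
from .paradigm import ClampSchedule

__all__ = [
    "PARAM_NAMES",
    "default_bounds",
    "params_from_vector",
    "FitSpec",
    "FitResult",
    "loss_sse",
    "fit_model",
    "compare_models",
    "bootstrap_parameter_ci",
    "participant_cycle_matrix",
]

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "motor_correction": ("A", "U"),
    "movement_reinforcement": ("A", "U", "A_prime", "s"),
    "adaptation_modulation": ("A", "U", "gamma_A", "gamma_u"),
    "dual_error": ("A_spe", "U_spe", "A_te", "U_te"),
    "mr_am": ("A", "U", "gamma_A", "gamma_u", "A_prime", "s"),
    "mr_de": ("A_spe", "U_spe", "A_te", "U_te", "A_prime", "s"),
}

_EPS = 1e-6


def default_bounds(model: str, clamp_deg: float) -> list[tuple[float, float]]:
    """Open-interval bounds per parameter, given the clamp size ``e``.

    Retention factors lie in (0, 1); update sizes in (0, e); hit-trial
    gains in (0, 5]; reinforcement increment s in (0, 1).
    """
    if clamp_deg <= 0:
        raise ValueError("clamp size must be positive to bound the update")
    per_name = {
        "A": (_EPS, 1 - _EPS),
        "A_spe": (_EPS, 1 - _EPS),
        "A_te": (_EPS, 1 - _EPS),
        "A_prime": (_EPS, 1 - _EPS),
        "U": (_EPS, clamp_deg - _EPS),
        "U_spe": (_EPS, clamp_deg - _EPS),
        "U_te": (_EPS, clamp_deg - _EPS),
        "gamma_A": (_EPS, 5.0),
        "gamma_u": (_EPS, 5.0),
        "s": (_EPS, 1 - _EPS),
    }
    return [per_name[name] for name in PARAM_NAMES[model]]


def params_from_vector(model: str, vec: Sequence[float]):
    """Build the model's parameter bundle from a flat vector."""
    v = list(map(float, vec))
    if model == "motor_correction":
        return M.StateSpaceParams(*v)
    if model == "movement_reinforcement":
        return (M.StateSpaceParams(v[0], v[1]), M.ReinforcementParams(v[2], v[3]))
    if model == "adaptation_modulation":
        return M.ModulationParams(M.StateSpaceParams(v[0], v[1]), v[2], v[3])
    if model == "dual_error":
        return M.DualErrorParams(*v)
    if model == "mr_am":
        return M.HybridParams(
            reinforcement=M.ReinforcementParams(v[4], v[5]),
            core=M.ModulationParams(M.StateSpaceParams(v[0], v[1]), v[2], v[3]),
        )
    if model == "mr_de":
        return M.HybridParams(
            reinforcement=M.ReinforcementParams(v[4], v[5]),
            core=M.DualErrorParams(*v[:4]),
        )
    raise ValueError(f"unknown model id {model!r}")


def _precompute(sched: ClampSchedule) -> tuple:
    """Cache the schedule arrays and clamp-cycle index map used per loss eval."""
    err = sched.is_clamp.astype(np.float64)
    hit = sched.hit.astype(np.int64)
    mask = err > 0
    cyc = sched.cycle[mask]
    order = np.unique(cyc)
    idx = np.searchsorted(order, cyc)
    counts = np.bincount(idx)
    return err, hit, mask, idx, counts


def _sim_cycle_means(model: str, vec: np.ndarray, pre: tuple) -> np.ndarray:
    """Clamp-cycle means of the model's motor output, via the compiled cores."""
    err, hit, mask, idx, counts = pre
    if model == "motor_correction":
        y = M._core_motor_correction(err, vec[0], vec[1])
    elif model == "movement_reinforcement":
        x = M._core_motor_correction(err, vec[0], vec[1])
        y, _, _ = M._blend_population_vector(x, hit, vec[2], vec[3])
    elif model == "adaptation_modulation":
        y = M._core_modulation(err, hit, vec[0], vec[1], vec[2], vec[3])
    elif model == "dual_error":
        xs, xt = M._core_dual_error(err, hit, vec[0], vec[1], vec[2], vec[3])
        y = xs + xt
    elif model == "mr_am":
        x = M._core_modulation(err, hit, vec[0], vec[1], vec[2], vec[3])
        y, _, _ = M._blend_population_vector(x, hit, vec[4], vec[5])
    elif model == "mr_de":
        xs, xt = M._core_dual_error(err, hit, vec[0], vec[1], vec[2], vec[3])
        y, _, _ = M._blend_population_vector(xs + xt, hit, vec[4], vec[5])
    else:
        raise ValueError(f"unknown model id {model!r}")
    return np.bincount(idx, weights=y[mask]) / counts


def _simulate_vec(model: str, vec: np.ndarray, sched: ClampSchedule) -> np.ndarray:
    """Clamp-cycle means of the model's motor output for a parameter vector."""
    return _sim_cycle_means(model, np.asarray(vec, float), _precompute(sched))


@dataclass
class FitSpec:
    """One (possibly multi-group) fitting problem.

    ``schedules`` and ``observed`` are parallel lists: one trial schedule
    and one clamp-phase cycle-mean array per group, aligned in cycle count.
    """

    model: str
    schedules: list[ClampSchedule]
    observed: list[np.ndarray]
    bounds: list[tuple[float, float]] | None = None
    n_starts: int = 10
    seed: int | None = 0
    warm_starts: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.model not in PARAM_NAMES:
            raise ValueError(f"unknown model id {self.model!r}")
        if len(self.schedules) != len(self.observed) or not self.schedules:
            raise ValueError("need one observed series per schedule")
        self.observed = [np.asarray(o, float) for o in self.observed]
        for sched, obs in zip(self.schedules, self.observed):
            n_clamp = sched.clamp_cycles().size
            if n_clamp != obs.size:
                raise ValueError(
                    f"observed series length {obs.size} does not match "
                    f"{n_clamp} clamp cycles in the schedule"
                )
        if self.bounds is None:
            e = max(float(np.max(s.clamp_deg)) for s in self.schedules)
            self.bounds = default_bounds(self.model, e)

    @property
    def k(self) -> int:
        return len(PARAM_NAMES[self.model])

    @property
    def n_obs(self) -> int:
        return int(sum(o.size for o in self.observed))


@dataclass
class FitResult:
    """Best-fitting parameters and fit diagnostics."""

    model: str
    params: object
    params_vector: np.ndarray
    param_names: tuple[str, ...]
    sse: float
    r2: float
    aic: float
    n_obs: int
    k: int
    start_losses: list[float] = field(default_factory=list)
    converged: bool = True

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.params_vector)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "params": self.params_dict(),
                "sse": self.sse,
                "r2": self.r2,
                "aic": self.aic,
                "n_obs": self.n_obs,
                "k": self.k,
                "start_losses": self.start_losses,
                "converged": self.converged,
            },
            indent=2,
        )


def loss_sse(model: str, params, spec: FitSpec) -> float:
    """Summed squared error over groups and clamp-cycle means (deg²).

    ``params`` may be a flat vector or a parameter bundle.  Additive over
    groups by construction.
    """
    is_bundle = hasattr(params, "__dataclass_fields__") or (
        isinstance(params, tuple)
        and any(hasattr(p, "__dataclass_fields__") for p in params)
    )
    vec = _vector_from_params(model, params) if is_bundle else np.asarray(params, float)
    total = 0.0
    for sched, obs in zip(spec.schedules, spec.observed):
        sim = _simulate_vec(model, vec, sched)
        total += float(((obs - sim) ** 2).sum())
    return total


def _vector_from_params(model: str, params) -> np.ndarray:
    if model == "motor_correction":
        return np.array([params.A, params.U])
    if model == "movement_reinforcement":
        ss, rp = params
        return np.array([ss.A, ss.U, rp.A_prime, rp.s])
    if model == "adaptation_modulation":
        return np.array([params.base.A, params.base.U, params.gamma_A, params.gamma_u])
    if model == "dual_error":
        return np.array([params.A_spe, params.U_spe, params.A_te, params.U_te])
    if model == "mr_am":
        c, r = params.core, params.reinforcement
        return np.array([c.base.A, c.base.U, c.gamma_A, c.gamma_u, r.A_prime, r.s])
    if model == "mr_de":
        c, r = params.core, params.reinforcement
        return np.array([c.A_spe, c.U_spe, c.A_te, c.U_te, r.A_prime, r.s])
    raise ValueError(f"unknown model id {model!r}")


def _goodness(spec: FitSpec, sse: float) -> tuple[float, float]:
    pooled = np.concatenate(spec.observed)
    sst = float(((pooled - pooled.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    n = spec.n_obs
    aic = n * np.log(max(sse, 1e-300) / n) + 2 * spec.k
    return r2, float(aic)


def fit_model(spec: FitSpec) -> FitResult:
    """Multi-start bounded least squares for one fitting problem.

    The first start is a neutral point (gains 1, reinforcement increment
    ≈0, moderate retention) so the nested-model basin is always explored;
    the remaining ``n_starts − 1`` are drawn uniformly inside the bounds
    with the spec's seed.  Each start is refined with bounded Powell (loss
    tolerance 1e−8) and the lowest-loss solution is returned with all
    per-start losses as diagnostics.
    """
    rng = np.random.default_rng(spec.seed)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    pres = [_precompute(s) for s in spec.schedules]

    def objective(vec: np.ndarray) -> float:
        vec = np.clip(vec, lo, hi)
        total = 0.0
        for pre, obs in zip(pres, spec.observed):
            sim = _sim_cycle_means(spec.model, vec, pre)
            total += float(((obs - sim) ** 2).sum())
        return total

    neutral_by_name = {
        "A": 0.95, "A_spe": 0.95, "A_te": 0.9, "A_prime": 0.9,
        "gamma_A": 1.0, "gamma_u": 1.0, "s": 1e-4,
    }
    names = PARAM_NAMES[spec.model]
    e_hi = max(b[1] for n, b in zip(names, spec.bounds) if n.startswith("U"))
    neutral = np.array([
        neutral_by_name.get(n, 0.1 * e_hi) for n in names
    ])
    neutral = np.clip(neutral, lo, hi)

    fixed_starts = [neutral] + [
        np.clip(np.asarray(w, float), lo, hi) for w in (spec.warm_starts or [])
    ]
    n_random = max(spec.n_starts - len(fixed_starts), 1)
    starts = fixed_starts + [
        lo + (hi - lo) * rng.uniform(0.05, 0.95, size=lo.size)
        for _ in range(n_random)
    ]

    best_vec = None
    best_loss = np.inf
    start_losses: list[float] = []
    any_success = False
    messages: list[str] = []
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Powell",
            bounds=list(zip(lo, hi)),
            options={"ftol": 1e-8, "xtol": 1e-8, "maxiter": 10_000},
        )
        start_losses.append(float(res.fun))
        any_success = any_success or bool(res.success)
        if not res.success:
            messages.append(str(res.message))
        if res.fun < best_loss:
            best_loss = float(res.fun)
            best_vec = np.clip(res.x, lo, hi)

    if best_vec is None or not np.isfinite(best_loss):
        raise RuntimeError(f"all starts failed to converge: {messages}")
    r2, aic = _goodness(spec, best_loss)
    return FitResult(
        model=spec.model,
        params=params_from_vector(spec.model, best_vec),
        params_vector=best_vec,
        param_names=PARAM_NAMES[spec.model],
        sse=best_loss,
        r2=r2,
        aic=aic,
        n_obs=spec.n_obs,
        k=spec.k,
        start_losses=start_losses,
        converged=any_success,
    )


def compare_models(
    model_ids: Sequence[str],
    schedules: list[ClampSchedule],
    observed: list[np.ndarray],
    n_starts: int = 10,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit each model to the same data and rank by AIC (ties: fewer k).

    Hybrids (and the reinforcement model) receive the already-fitted nested
    model's solution as an extra warm start, so a hybrid can never rank
    below its own nested special case for want of a good basin.  Returns
    the comparison table (model, k, r2, aic, ordered best-first) and the
    individual fit results.
    """
    nested_parent = {
        "movement_reinforcement": "motor_correction",
        "mr_am": "adaptation_modulation",
        "mr_de": "dual_error",
    }
    fits: dict[str, FitResult] = {}
    rows = []
    order = sorted(range(len(model_ids)),
                   key=lambda i: model_ids[i] in nested_parent)
    for i in order:
        mid = model_ids[i]
        warm = None
        parent = nested_parent.get(mid)
        if parent in fits:
            pv = fits[parent].params_vector
            warm = [np.concatenate([pv, [0.9, 1e-4]])]
        child_seed = None if seed is None else seed + 1000 * i
        spec = FitSpec(mid, schedules, observed, n_starts=n_starts,
                       seed=child_seed, warm_starts=warm)
        fit = fit_model(spec)
        fits[mid] = fit
        rows.append({"model": mid, "k": fit.k, "r2": fit.r2, "aic": fit.aic})
    table = pd.DataFrame(rows).sort_values(
        ["aic", "k"], kind="stable"
    ).reset_index(drop=True)
    return table, fits


def participant_cycle_matrix(cycle_series: pd.DataFrame, clamp_only: bool = True) -> np.ndarray:
    """Participants × cycles matrix of cycle means from a per-participant series."""
    cs = cycle_series
    if clamp_only:
        cs = cs[cs["block"] == "clamp"]
    mat = cs.pivot(index="participant", columns="cycle", values="hand_angle")
    return mat.to_numpy(dtype=float)


def bootstrap_parameter_ci(
    model: str,
    schedules: list[ClampSchedule],
    participant_matrices: list[np.ndarray],
    n_boot: int = 1000,
    ci: float = 95.0,
    seed: int | None = 0,
    n_starts: int = 5,
) -> dict:
    """Percentile bootstrap CIs for the fitted parameters.

    Each replicate resamples participants with replacement *within each
    group*, averages their clamp-cycle series into new group-level learning
    functions, and refits the model to all groups simultaneously.  Returns
    per-parameter (lo, hi) plus the replicate parameter matrix.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    names = PARAM_NAMES[model]
    draws = np.empty((n_boot, len(names)))
    for b in range(n_boot):
        observed = []
        for mat in participant_matrices:
            idx = rng.integers(0, mat.shape[0], size=mat.shape[0])
            observed.append(np.nanmean(mat[idx], axis=0))
        spec = FitSpec(
            model, schedules, observed,
            n_starts=n_starts,
            seed=None if seed is None else int(rng.integers(0, 2**31 - 1)),
        )
        draws[b] = fit_model(spec).params_vector
    alpha = (100.0 - ci) / 2.0
    lo = np.percentile(draws, alpha, axis=0)
    hi = np.percentile(draws, 100.0 - alpha, axis=0)
    return {
        "param_names": names,
        "ci": {n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)},
        "draws": draws,
        "n_boot": n_boot,
        "seed": seed,
    }
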