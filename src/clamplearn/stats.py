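"""Group-comparison statistics for participant-level metrics.

The workhorse is a label-permutation test on the difference between group
means (two groups) or the one-way ANOVA F statistic (more groups), with the
+1-smoothed Monte-Carlo p-value ``(count(null ≥ observed) + 1)/(n_perm + 1)``.
The default null is generated by shuffling group assignments without
replacement; a bootstrap null (resampling the pooled values with
replacement) is available as an option.  Classical t-tests/ANOVA and the
standard effect sizes (Cohen's d, d_z, η²) are provided as thin wrappers so
a full statistics block can be emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "permutation_test",
    "cohens_d",
    "d_z",
    "eta_squared",
    "effect_sizes",
    "t_test",
    "one_way_anova",
]


@dataclass(frozen=True)
class PermutationResult:
    test: str
    statistic: float
    p: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in out):
        raise ValueError("empty group")
    return out


def _mean_difference(groups: list[np.ndarray]) -> float:
    return float(groups[0].mean() - groups[1].mean())


def _anova_f(groups: list[np.ndarray]) -> float:
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = sum(g.size for g in groups) - len(groups)
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return float((ss_between / df_b) / (ss_within / df_w))


def permutation_test(
    groups,
    statistic: str = "mean_difference",
    n_perm: int = 10_000,
    seed: int | None = None,
    null: str = "shuffle",
) -> PermutationResult:
    """Monte-Carlo permutation test on group assignment.

    ``mean_difference`` (exactly two groups) is two-sided on |Δmean|;
    ``anova_F`` (two or more groups) is upper-tailed.  ``null='shuffle'``
    permutes labels without replacement; ``null='bootstrap'`` draws each
    permuted group from the pooled values with replacement.
    """
    gs = _as_groups(groups)
    if statistic == "mean_difference":
        if len(gs) != 2:
            raise ValueError("mean_difference requires exactly two groups")
        stat_fn, observed = _mean_difference, abs(_mean_difference(gs))
        two_sided = True
    elif statistic == "anova_F":
        if len(gs) < 2:
            raise ValueError("anova_F requires at least two groups")
        stat_fn, observed = _anova_f, _anova_f(gs)
        two_sided = False
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    # the null depends only on the pooled value multiset and the group-size
    # multiset; sorting both makes p invariant to group labeling at fixed seed
    pooled = np.sort(np.concatenate(gs))
    sizes = sorted(g.size for g in gs)
    splits = np.cumsum(sizes)[:-1]
    rng = np.random.default_rng(seed)
    # ties count toward the null (conservative exact-test convention);
    # the epsilon keeps float-order noise from splitting exact ties
    tie_eps = 1e-9 * max(1.0, abs(observed))
    count = 0
    for _ in range(n_perm):
        if null == "shuffle":
            perm = rng.permutation(pooled)
        elif null == "bootstrap":
            perm = rng.choice(pooled, size=pooled.size, replace=True)
        else:
            raise ValueError(f"unknown null {null!r}")
        parts = np.split(perm, splits)
        val = stat_fn(parts)
        if two_sided:
            val = abs(val)
        if val >= observed - tie_eps:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(statistic, float(observed), float(p), n_perm, seed)


def cohens_d(a, b) -> float:
    """Pooled-SD Cohen's d between two independent groups.

    Infinite (signed) when the pooled SD is zero but the means differ;
    NaN when both are degenerate.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        return float(np.sign(diff) * np.inf) if diff != 0 else float("nan")
    return float(diff / np.sqrt(pooled_var))


def d_z(diffs) -> float:
    """Within-subject effect size mean(diff)/SD(diff); NaN when SD is zero."""
    d = np.asarray(diffs, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float(d.mean() / sd)


def eta_squared(groups) -> float:
    """η² = SS_between / SS_total for a one-way layout."""
    gs = _as_groups(groups)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_total = ((np.concatenate(gs) - grand) ** 2).sum()
    if ss_total == 0:
        return float("nan")
    return float(ss_between / ss_total)


def effect_sizes(groups=None, paired=None) -> dict:
    """Standard effect sizes for a group layout and/or paired differences.

    Degenerate (zero-variance) cases surface as NaN/inf with an
    ``undefined`` flag rather than being silently zeroed.
    """
    out: dict = {}
    if groups is not None:
        gs = _as_groups(groups)
        if len(gs) == 2:
            out["cohens_d"] = cohens_d(gs[0], gs[1])
        out["eta_squared"] = eta_squared(gs)
        # partial η² coincides with η² in the one-way between-subject layout
        out["partial_eta_squared"] = out["eta_squared"]
    if paired is not None:
        out["d_z"] = d_z(paired)
    out["undefined"] = any(
        not np.isfinite(v) for v in out.values() if isinstance(v, float)
    )
    return out


def t_test(a, b=None, paired: bool = False) -> dict:
    """Conventional two-tailed t-test (one-sample on diffs when paired)."""
    if paired or b is None:
        d = np.asarray(a, float) if b is None else np.asarray(a, float) - np.asarray(b, float)
        t, p = sps.ttest_1samp(d, 0.0)
        df = d.size - 1
    else:
        t, p = sps.ttest_ind(a, b)
        df = len(a) + len(b) - 2
    return {"t": float(t), "df": int(df), "p": float(p)}


def one_way_anova(groups) -> dict:
    """Conventional one-way ANOVA F and p."""
    gs = _as_groups(groups)
    f, p = sps.f_oneway(*gs)
    return {"F": float(f), "p": float(p), "eta_squared": eta_squared(gs)}
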