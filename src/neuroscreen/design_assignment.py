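"""Treatment-group assignment by F-minimisation over random candidates.

Before a treatment experiment, arrays whose baseline firing sits more than
2 SDs below the median of the sample set are dropped as inactive. The
remaining pool is then randomly split into g groups of n arrays, i times
over, and each candidate split is scored by the one-way ANOVA F statistic
of baseline log10 firing by group; the split with the lowest F (the most
balanced baseline) is the assignment used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (DegenerateInputError, InfeasibleDesignError,
                         InvalidConfigError)


@dataclass
class AssignmentPlan:
    """A group assignment and the baseline balance it achieved."""

    assignment: pd.Series  # index: array id, value: group label
    f_statistic: float
    n_candidates: int
    seed: int

    def groups(self) -> dict[str, list[str]]:
        return {g: list(idx) for g, idx in
                self.assignment.groupby(self.assignment).groups.items()}


def select_active(metrics: pd.DataFrame) -> pd.DataFrame:
    """Arrays with log10hz >= median - 2 x sample SD of the full set.

    ``metrics`` needs columns ``array`` and ``log10hz``. The median and SD
    are computed on the full sample set before any exclusion.
    """
    if len(metrics) < 2:
        raise DegenerateInputError("need at least 2 arrays to select a pool")
    x = metrics["log10hz"].to_numpy(dtype=float)
    cutoff = np.median(x) - 2.0 * x.std(ddof=1)
    return metrics.loc[x >= cutoff].copy()


def oneway_f(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F of values by group label.

    Zero between-group and zero within-group variance defines F = 0.
    """
    values = np.asarray(values, dtype=float)
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    n = values.size
    grand = values.mean()
    group_n = np.bincount(inverse, minlength=k)
    group_sum = np.bincount(inverse, weights=values, minlength=k)
    group_mean = group_sum / group_n
    ss_between = float(np.sum(group_n * (group_mean - grand) ** 2))
    ss_within = float(np.sum((values - group_mean[inverse]) ** 2))
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        return 0.0 if ss_between == 0.0 else float("inf")
    return (ss_between / df_b) / (ss_within / df_w)


def assign_groups(active: pd.DataFrame, n_groups: int, group_size: int,
                  n_candidates: int = 10_000, seed: int = 0,
                  group_labels: list[str] | None = None) -> AssignmentPlan:
    """Minimum-F assignment of g x n arrays into g groups of n.

    Candidates are sampled independently (with replacement across
    candidates); when the active pool exceeds g x n, the assigned subset is
    itself re-drawn per candidate. Ties on F keep the first candidate.
    """
    if n_groups < 2:
        raise InvalidConfigError("need at least 2 treatment groups")
    if n_candidates < 1:
        raise InvalidConfigError("need at least 1 candidate assignment")
    pool = active["array"].to_numpy()
    values = active["log10hz"].to_numpy(dtype=float)
    need = n_groups * group_size
    if need > pool.size:
        raise InfeasibleDesignError(
            f"design needs {need} arrays but the active pool has {pool.size}")
    if group_labels is None:
        group_labels = [f"G{g + 1}" for g in range(n_groups)]
    labels = np.repeat(np.asarray(group_labels, dtype=object), group_size)

    rng = np.random.default_rng(seed)
    best_f = np.inf
    best_idx: np.ndarray | None = None
    for _ in range(n_candidates):
        idx = rng.choice(pool.size, size=need, replace=False)
        f = oneway_f(values[idx], labels)
        if f < best_f:
            best_f = f
            best_idx = idx
    assert best_idx is not None
    assignment = pd.Series(labels, index=pool[best_idx], name="group")
    assignment.index.name = "array"
    return AssignmentPlan(assignment=assignment, f_statistic=float(best_f),
                          n_candidates=n_candidates, seed=seed)
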