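"""Monte-Carlo power surface for the correlated baseline/follow-up design.

A pool of untreated baseline firing values (log10 Hz) stands for the
recordings at t0 (vector A); a follow-up vector B with sample correlation
exactly rho is built once per run by
``B = rho*A + A_perp*sqrt(1 - rho^2)``. Each simulated treatment draws
2n distinct arrays from the paired pool, splits them into control and
treatment groups of n, subtracts the effect size from the treatment
group's t1 values, fits the 2x2 ANCOVA (group x time with interaction)
and extracts the Tukey-adjusted p of the control-vs-treatment comparison
at t1. Power in a (sample size, effect size) cell is the fraction of
iterations with p < alpha.

Because the interaction model is saturated, the Tukey decision
"adjusted p < alpha" is identical to "q > q_crit(alpha; k=4, df)" on the
studentized-range scale; :func:`simulate_cell` uses that closed form,
vectorised over iterations, and its equivalence with the literal
``ancova_fit`` + ``tukey_posthoc`` route is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InfeasibleDesignError, InvalidConfigError
from .synthetic_data import paired_followup

DEFAULT_SAMPLE_SIZES = tuple(range(3, 17))  # 3..16 arrays per group
DEFAULT_EFFECT_SIZES = tuple(round(0.1 * k, 1) for k in range(1, 21))  # 0.1..2.0


@dataclass(frozen=True)
class PowerConfig:
    """Grid and sampling parameters for the power surface."""

    pool: np.ndarray  # baseline log10 Hz values (e.g. 1272 untreated arrays)
    rho: float = 0.8
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    effect_sizes: tuple[float, ...] = DEFAULT_EFFECT_SIZES
    iterations_per_cell: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidConfigError(f"rho must be in [0, 1], got {self.rho}")
        if self.iterations_per_cell < 1:
            raise InvalidConfigError("iterations_per_cell must be >= 1")
        if any(e < 0 for e in self.effect_sizes):
            raise InvalidConfigError("effect sizes must be non-negative")
        pool = np.asarray(self.pool, dtype=float)
        if pool.size < 2 * max(self.sample_sizes) + 3:
            raise InfeasibleDesignError(
                f"pool of {pool.size} arrays cannot support group size "
                f"{max(self.sample_sizes)}")
        object.__setattr__(self, "pool", pool)


@dataclass(frozen=True)
class PowerCell:
    """Power in one (sample size, effect size) cell of the grid."""

    sample_size: int
    effect_size: float
    n_iterations: int
    n_significant: int

    @property
    def power(self) -> float:
        return self.n_significant / self.n_iterations


def grid_total_treatments(config: PowerConfig) -> int:
    """Planned number of simulated treatments for the full grid, without
    running any simulation: cells x iterations per cell."""
    return (len(config.sample_sizes) * len(config.effect_sizes)
            * config.iterations_per_cell)


def build_paired_pool(config: PowerConfig) -> tuple[np.ndarray, np.ndarray]:
    """The (t0, t1) paired pool, constructed once per grid run."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(0xB,)))
    a = config.pool
    b = paired_followup(a, config.rho, rng)
    return a, b


def _cell_seed(config: PowerConfig, sample_size: int, effect_size: float) -> int:
    idx_n = config.sample_sizes.index(sample_size) if sample_size in config.sample_sizes else sample_size
    idx_e = int(round(effect_size * 1000))
    ss = np.random.SeedSequence(entropy=int(config.seed),
                                spawn_key=(idx_n, idx_e))
    return ss


def simulate_cell(config: PowerConfig, sample_size: int, effect_size: float,
                  paired: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> PowerCell:
    """Simulate one grid cell.

    Per iteration, 2n distinct arrays are drawn without replacement from
    the paired pool (control and treatment disjoint); the treatment group's
    t1 values are offset by -effect_size (the treatments in this design
    reduce firing; the grid reports |effect|). Significance is the Tukey
    control-vs-treatment comparison at t1 with adjusted p < alpha.
    """
    a, b = build_paired_pool(config) if paired is None else paired
    n = int(sample_size)
    if 2 * n > a.size:
        raise InfeasibleDesignError(
            f"cannot draw {2 * n} distinct arrays from a pool of {a.size}")
    iters = config.iterations_per_cell
    rng = np.random.default_rng(_cell_seed(config, sample_size, effect_size))

    # 2n distinct indices per iteration: partial argpartition of random keys
    keys = rng.random((iters, a.size))
    idx = np.argpartition(keys, 2 * n, axis=1)[:, : 2 * n]
    ctrl, trt = idx[:, :n], idx[:, n:]

    cells = np.stack([a[ctrl], a[trt], b[ctrl], b[trt] - effect_size], axis=1)
    # cells: (iters, 4, n) = (ctrl,t0), (trt,t0), (ctrl,t1), (trt,t1)
    means = cells.mean(axis=2)
    sse = ((cells - means[:, :, None]) ** 2).sum(axis=(1, 2))
    df = 4 * n - 4
    s2 = sse / df
    q = np.abs(means[:, 2] - means[:, 3]) / np.sqrt(s2 / n)
    q_crit = stats.studentized_range.isf(config.alpha, 4, df)
    n_sig = int(np.count_nonzero(q > q_crit))
    return PowerCell(sample_size=n, effect_size=float(effect_size),
                     n_iterations=iters, n_significant=n_sig)


def run_power_grid(config: PowerConfig) -> tuple[pd.DataFrame, int]:
    """Simulate every (sample size, effect size) cell of the grid.

    Returns the grid as a frame (sample_size, effect_size, n_iter, n_sig,
    power) plus the total number of simulated treatments. Cells are
    independent given their child seeds, so the grid is reproducible
    cell-by-cell.
    """
    paired = build_paired_pool(config)
    rows = []
    total = 0
    for n in config.sample_sizes:
        for e in config.effect_sizes:
            cell = simulate_cell(config, n, e, paired=paired)
            total += cell.n_iterations
            rows.append({"sample_size": cell.sample_size,
                         "effect_size": cell.effect_size,
                         "n_iter": cell.n_iterations,
                         "n_sig": cell.n_significant,
                         "power": cell.power})
    return pd.DataFrame(rows), total
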