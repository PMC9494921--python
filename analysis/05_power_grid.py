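"""Monte-Carlo power surface for the correlated pre/post design.

The full design (sample sizes 3-16, effect sizes 0.1-2.0 in steps of 0.1,
5000 iterations per cell) totals 1.4 million simulated treatments; the
planner verifies that count, and the grid itself is run at a desk-scale
200 iterations per cell (pass --full for the 5000-iteration grid).
"""

import argparse
from pathlib import Path

import numpy as np

from neuroscreen import io
from neuroscreen.power_simulation import (PowerConfig,
                                          grid_total_treatments,
                                          run_power_grid)
from neuroscreen.synthetic_data import SimConfig, gen_paired_log10hz

OUT = Path("results")
SEED = 1


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--full", action="store_true",
                        help="5000 iterations per cell")
    args = parser.parse_args()

    # pool of 1272 untreated baseline recordings, as in the design
    pool, _ = gen_paired_log10hz(SimConfig(seed=SEED, n_arrays=1272))
    full = PowerConfig(pool=pool, seed=SEED)
    print(f"full design: {len(full.sample_sizes)} sizes x "
          f"{len(full.effect_sizes)} effects x {full.iterations_per_cell} "
          f"iterations = {grid_total_treatments(full):,} treatments")

    iters = 5000 if args.full else 200
    config = PowerConfig(pool=pool, iterations_per_cell=iters, seed=SEED)
    grid, total = run_power_grid(config)
    io.write_tsv(grid, OUT / "power_grid.tsv")
    print(f"simulated {total:,} treatments at {iters}/cell")

    piv = grid.pivot(index="sample_size", columns="effect_size",
                     values="power")
    for effect in (0.5, 1.0, 2.0):
        n80 = piv.index[piv[effect] >= 0.8]
        where = f"n >= {n80.min()}" if len(n80) else "not reached by n = 16"
        print(f"  80% power at effect {effect} log10Hz: {where}")


if __name__ == "__main__":
    main()
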