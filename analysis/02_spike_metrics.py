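"""Spike events -> per-array firing metrics.

Pools every crossing threshold on the plate, sets the exclusion limit at
mean + 3 SD, drops the events above it (the planted high-noise
electrodes), and reports MFR = n/s with log10[(n + 1)/s] per array.
"""

from pathlib import Path

from neuroscreen import io
from neuroscreen.mea_metrics import exclude_noise_events, table_to_metrics

IN = Path("results/inputs")
OUT = Path("results")
DURATION_S = 1800.0


def main() -> None:
    events = io.read_spikes(IN / "spikes.csv")
    kept, limit = exclude_noise_events(events)
    removed = len(events) - len(kept)
    print(f"noise exclusion: limit {limit:.1f} uV, removed {removed} of "
          f"{len(events)} events ({100 * removed / len(events):.2f}%)")

    wells = sorted(events["well"].unique())
    metrics = table_to_metrics(kept, DURATION_S, wells=wells)
    io.write_array_metrics(metrics, OUT / "array_metrics.tsv")
    print(f"array_metrics.tsv: {len(metrics)} arrays, median log10 MFR "
          f"{metrics['log10hz'].median():.3f} "
          f"(range {metrics['log10hz'].min():.3f} to "
          f"{metrics['log10hz'].max():.3f})")


if __name__ == "__main__":
    main()
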