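"""Generate the study-scale synthetic inputs.

Writes spikes.csv (48 arrays x 8 electrodes, 30-min recordings), the
1841-protein x 43-individual LFQ matrix over 2 LC-MS runs, the phenotype
table (19 MEA / 27 NI individuals, 4 tested in both), and the Abeta/tau
measure panel, all under results/inputs/.
"""

from pathlib import Path

from neuroscreen import io
from neuroscreen.synthetic_data import (SimConfig, gen_lfq_matrix,
                                        gen_measures, gen_phenotypes,
                                        gen_spike_table)

SEED = 1
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=SEED)

    spikes, spike_truth = gen_spike_table(config)
    io.write_spikes(spikes, OUT / "spikes.csv")
    print(f"spikes.csv: {len(spikes)} events on {config.n_arrays} arrays; "
          f"{len(spike_truth.noise_electrodes)} high-noise electrodes planted")

    lfq, lfq_truth = gen_lfq_matrix(config)
    io.write_lfq(lfq, OUT / "lfq.tsv", OUT / "samples.tsv")
    frac = lfq.n_missing() / lfq.total_observations()
    print(f"lfq.tsv: {lfq.n_proteins} proteins x {lfq.n_individuals} "
          f"individuals, {100 * frac:.2f}% missing, run offsets "
          f"{[round(float(o), 3) for o in lfq_truth.run_offsets]} log2")

    pheno, _ = gen_phenotypes(config)
    io.write_phenotypes(pheno, OUT / "phenotypes.tsv")
    print("phenotypes.tsv:", pheno["assay"].value_counts().to_dict())

    measures, _ = gen_measures(config)
    io.write_measures(measures, OUT / "measures.tsv")
    print(f"measures.tsv: {measures.shape[1]} Abeta/tau measures for "
          f"{measures.shape[0]} individuals")


if __name__ == "__main__":
    main()
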