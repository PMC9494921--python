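"""The protein-phenotype screen and the shared-hits table.

Correlates each retained protein with % neurite integrity (n = 27) and
with the firing effect (n = 19) by Spearman rho, converts to the modified
Fisher z for p-values, Holm-adjusts within each family, ranks by |rho|
(waterfall order) and intersects the two assays at unadjusted p < 0.05.
Also correlates the Abeta/tau measure panel with both assay metrics.
"""

from pathlib import Path

from neuroscreen import io
from neuroscreen.phenotype_screen import (PhenotypeVector,
                                          measure_correlations, screen,
                                          shared_hits)
from neuroscreen.proteome_prep import (filter_missing, remove_run_effect,
                                       vsn_log2_normalize)

IN = Path("results/inputs")
OUT = Path("results")


def main() -> None:
    matrix = io.read_lfq(IN / "lfq.tsv", IN / "samples.tsv")
    filtered = filter_missing(remove_run_effect(vsn_log2_normalize(matrix)))
    pheno = io.read_phenotypes(IN / "phenotypes.tsv")

    ni = pheno[pheno["assay"].isin(["NI", "MEA/NI"])]
    mea = pheno[pheno["assay"].isin(["MEA", "MEA/NI"])]
    pv_ni = PhenotypeVector(ni.set_index("individual")["ni_percent"], "NI")
    pv_mea = PhenotypeVector(mea.set_index("individual")["dlog10hz"], "MEA")

    res_ni = screen(filtered, pv_ni)
    res_mea = screen(filtered, pv_mea)
    io.write_tsv(res_ni, OUT / "screen_ni.tsv")
    io.write_tsv(res_mea, OUT / "screen_mea.tsv")
    for name, res in (("NI", res_ni), ("MEA", res_mea)):
        top = res.iloc[0]
        print(f"{name} screen: {len(res)} proteins, top |rho| = "
              f"{top['rho']:+.2f} ({top['feature']}, p = {top['p']:.2g}); "
              f"{(res['p'] < 0.05).sum()} at unadjusted p < 0.05, "
              f"{(res['p_holm'] < 0.05).sum()} after Holm")

    hits = shared_hits(res_ni, res_mea, p_threshold=0.05)
    io.write_tsv(hits, OUT / "shared_hits.tsv")
    print(f"shared hits (p < 0.05 in both assays): {len(hits)}")
    toxic = hits[(hits["rho_ni"] < 0) & (hits["rho_mea"] < 0)]
    print(f"  concordant neurotoxic-associated: {list(toxic['feature'])}")

    measures = io.read_measures(IN / "measures.tsv")
    mcorr = measure_correlations(measures, {"NI": pv_ni, "MEA": pv_mea})
    io.write_tsv(mcorr, OUT / "measure_corr.tsv")
    sig = mcorr[mcorr["p"] < 0.05]
    print(f"measure correlations: {len(sig)} of {len(mcorr)} "
          "(measure, assay) pairs at p < 0.05")


if __name__ == "__main__":
    main()
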