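"""Proteome preparation and structure.

Variance-stabilising normalisation to the log2 scale, per-protein LC-MS
run-effect removal, the >= 39-of-43 quantification filter, protein-mean
imputation for clustering, AD vs LP-NCI differential expression
(Welch + two-stage step-up FDR), complete-linkage clustering on Spearman
distance with the cluster-vs-diagnosis chi-squared, and PCA.
"""

from pathlib import Path

import pandas as pd

from neuroscreen import io
from neuroscreen.proteome_prep import (cluster_category_test, diff_expr,
                                       filter_missing, hcluster_individuals,
                                       impute_protein_means,
                                       pca_individuals, remove_run_effect,
                                       vsn_log2_normalize)

IN = Path("results/inputs")
OUT = Path("results")


def main() -> None:
    matrix = io.read_lfq(IN / "lfq.tsv", IN / "samples.tsv")
    norm = vsn_log2_normalize(matrix)
    corrected = remove_run_effect(norm)
    filtered = filter_missing(corrected, max_missing=4)
    print(f"filter: {filtered.n_proteins} of {matrix.n_proteins} proteins "
          f"quantified in >= {matrix.n_individuals - 4} of "
          f"{matrix.n_individuals} individuals")
    filtered.values.to_csv(OUT / "normalized.tsv", sep="\t",
                           index_label="protein")

    imputed, frac = impute_protein_means(filtered)
    print(f"imputation for clustering: {100 * frac:.2f}% of "
          f"{filtered.total_observations():,} retained observations")

    de = diff_expr(filtered, ("AD", "LP-NCI"))
    io.write_tsv(pd.DataFrame([vars(r) for r in de]), OUT / "de_results.tsv")
    n_sig = sum(r.significant for r in de)
    print(f"differential expression AD vs LP-NCI: {n_sig} of {len(de)} "
          "proteins at q < 0.05")

    labels, _ = hcluster_individuals(imputed, k=3)
    io.write_tsv(labels.rename_axis("individual").reset_index(),
                 OUT / "clusters.tsv")
    chi2, p, table = cluster_category_test(labels, imputed.categories)
    print(f"cluster x diagnosis chi-squared = {chi2:.2f}, p = {p:.3g}")
    print(table.to_string())

    scores, evr = pca_individuals(imputed)
    io.write_tsv(scores.rename_axis("individual").reset_index(),
                 OUT / "pca_scores.tsv")
    print(f"PCA: PC1 {100 * evr[0]:.1f}%, PC2 {100 * evr[1]:.1f}% of "
          "variance")


if __name__ == "__main__":
    main()
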