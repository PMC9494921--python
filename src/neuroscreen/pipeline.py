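"""End-to-end pipeline: synthesis (optional) -> spike metrics -> group
assignment -> treatment-effect models -> proteome preparation -> the
protein-phenotype screen, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .design_assignment import assign_groups, select_active
from .effect_models import ancova_fit, find_contrast, lme_effects, tukey_posthoc
from .exceptions import InvalidInputError
from .mea_metrics import exclude_noise_events, table_to_metrics
from .phenotype_screen import (PhenotypeVector, measure_correlations, screen,
                               shared_hits)
from .proteome_prep import (cluster_category_test, diff_expr, filter_missing,
                            hcluster_individuals, impute_protein_means,
                            pca_individuals, remove_run_effect,
                            vsn_log2_normalize)
from .synthetic_data import (SimConfig, gen_lfq_matrix, gen_measures,
                             gen_phenotypes, gen_spike_table, paired_followup,
                             child_rng)


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters with the study's defaults, plus file locations."""

    out_dir: str = "results"
    seed: int = 0
    synthesize: bool = False
    # input files (written by synth when synthesize is set)
    spikes: str = "spikes.csv"
    lfq: str = "lfq.tsv"
    samples: str = "samples.tsv"
    phenotypes: str = "phenotypes.tsv"
    measures: str = "measures.tsv"
    # stage parameters (study defaults)
    duration_s: float = 1800.0
    noise_sd: float = 3.0  # plate-level exclusion at mean + 3 SD
    active_sd: float = 2.0  # activity cutoff at median - 2 SD
    n_groups: int = 4
    group_size: int = 8
    n_candidates: int = 10_000
    treatment_rho: float = 0.8
    max_missing: int = 4
    n_clusters: int = 3
    alpha: float = 0.05
    sim: SimConfig = field(default_factory=SimConfig)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a report dict and writes all stage
    outputs plus ``manifest.json`` under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    t0 = time.time()

    sim = replace(config.sim, seed=config.seed)

    # --- inputs -----------------------------------------------------------
    paths = {name: out / getattr(config, name)
             for name in ("spikes", "lfq", "samples", "phenotypes",
                          "measures")}
    if config.synthesize:
        spikes_df, spike_truth = gen_spike_table(sim)
        io.write_spikes(spikes_df, paths["spikes"])
        lfq_matrix, _ = gen_lfq_matrix(sim)
        io.write_lfq(lfq_matrix, paths["lfq"], paths["samples"])
        pheno_df, _ = gen_phenotypes(sim)
        io.write_phenotypes(pheno_df, paths["phenotypes"])
        measures_df, _ = gen_measures(sim)
        io.write_measures(measures_df, paths["measures"])
    for name, p in paths.items():
        if not p.exists():
            raise InvalidInputError(
                f"missing input file {p}; run with synthesize=True or "
                "provide it")

    spikes_df = io.read_spikes(paths["spikes"])
    lfq_matrix = io.read_lfq(paths["lfq"], paths["samples"])
    pheno_df = io.read_phenotypes(paths["phenotypes"])
    measures_df = io.read_measures(paths["measures"])

    # --- spike metrics ----------------------------------------------------
    kept, limit = exclude_noise_events(spikes_df)
    wells = sorted(spikes_df["well"].unique())
    metrics = table_to_metrics(kept, config.duration_s, wells=wells)
    io.write_array_metrics(metrics, out / "array_metrics.tsv")
    report["stages"]["mea_metrics"] = {
        "n_events": int(len(spikes_df)), "n_kept": int(len(kept)),
        "noise_limit_uV": float(limit), "n_arrays": len(wells)}

    # --- treatment-group assignment --------------------------------------
    active = select_active(metrics)
    plan = assign_groups(active, config.n_groups, config.group_size,
                         n_candidates=config.n_candidates, seed=config.seed)
    assignment = plan.assignment.reset_index()
    io.write_tsv(assignment, out / "assignment.tsv")
    (out / "assignment_report.json").write_text(json.dumps({
        "f_statistic": plan.f_statistic, "n_candidates": plan.n_candidates,
        "seed": plan.seed}, indent=2) + "\n")
    report["stages"]["design_assignment"] = {
        "n_active": len(active), "f_statistic": plan.f_statistic}

    # --- treatment-effect models on the assigned arrays -------------------
    long = _simulated_treatment_panel(config, sim, metrics, plan, pheno_df)
    contrasts = []
    control = "G1"
    for g in sorted(set(plan.assignment) - {control}):
        sub = long[long["group"].isin([control, g])]
        fit = ancova_fit(sub)
        res = find_contrast(tukey_posthoc(fit), f"{g}:post", f"{control}:post")
        contrasts.append({"comparison": res.comparison,
                          "estimate": res.estimate, "se": res.se,
                          "p_adj": res.p_adj})
    contrasts_df = pd.DataFrame(contrasts)
    io.write_tsv(contrasts_df, out / "contrasts.tsv")
    lme = lme_effects(long.rename(columns={"group": "individual"}),
                      fixed="individual")
    io.write_tsv(lme.effects, out / "effects.tsv")
    report["stages"]["effect_models"] = {
        "n_contrasts": len(contrasts_df),
        "lme_random_factors": lme.random_factors}

    # --- proteome preparation ---------------------------------------------
    norm = vsn_log2_normalize(lfq_matrix)
    corrected = remove_run_effect(norm)
    filtered = filter_missing(corrected, max_missing=config.max_missing)
    imputed, imputed_fraction = impute_protein_means(filtered)
    de = diff_expr(filtered, ("AD", "LP-NCI"))
    io.write_tsv(pd.DataFrame([vars(r) for r in de]), out / "de_results.tsv")
    labels, _ = hcluster_individuals(imputed, k=config.n_clusters)
    chi2 = p_chi2 = float("nan")
    if imputed.categories is not None:
        try:
            chi2, p_chi2, _ = cluster_category_test(labels,
                                                    imputed.categories)
        except InvalidInputError:
            pass
    io.write_tsv(labels.reset_index().rename(
        columns={"index": "individual"}), out / "clusters.tsv")
    scores, evr = pca_individuals(imputed)
    io.write_tsv(scores.reset_index().rename(columns={"index": "individual"}),
                 out / "pca_scores.tsv")
    report["stages"]["proteome_prep"] = {
        "n_proteins_raw": lfq_matrix.n_proteins,
        "n_proteins_filtered": filtered.n_proteins,
        "imputed_fraction": imputed_fraction,
        "n_de_significant": sum(r.significant for r in de),
        "cluster_chi2": chi2, "cluster_chi2_p": p_chi2,
        "pc1_var": float(evr[0]) if len(evr) else float("nan")}

    # --- protein-phenotype screen -----------------------------------------
    ni = pheno_df[pheno_df["assay"].isin(["NI", "MEA/NI"])]
    mea = pheno_df[pheno_df["assay"].isin(["MEA", "MEA/NI"])]
    pv_ni = PhenotypeVector(
        values=ni.set_index("individual")["ni_percent"], assay="NI")
    pv_mea = PhenotypeVector(
        values=mea.set_index("individual")["dlog10hz"], assay="MEA")
    screen_ni = screen(filtered, pv_ni)
    screen_mea = screen(filtered, pv_mea)
    hits = shared_hits(screen_ni, screen_mea, p_threshold=config.alpha)
    mcorr = measure_correlations(measures_df,
                                 {"NI": pv_ni, "MEA": pv_mea})
    io.write_tsv(screen_ni, out / "screen_ni.tsv")
    io.write_tsv(screen_mea, out / "screen_mea.tsv")
    io.write_tsv(hits, out / "shared_hits.tsv")
    io.write_tsv(mcorr, out / "measure_corr.tsv")
    report["stages"]["phenotype_screen"] = {
        "n_screened_ni": len(screen_ni), "n_screened_mea": len(screen_mea),
        "n_shared_hits": len(hits),
        "top_shared": list(hits["feature"].head(5))}

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": "neuroscreen", "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("sim",)},
        "sim": asdict(sim),
        "input_hashes": {name: _sha256(p) for name, p in paths.items()},
        "elapsed_s": round(time.time() - t0, 3),
    }
    io.write_manifest(manifest, out / "manifest.json")
    report["manifest"] = manifest
    return report


def _simulated_treatment_panel(config: PipelineConfig, sim: SimConfig,
                               metrics: pd.DataFrame, plan,
                               pheno_df: pd.DataFrame) -> pd.DataFrame:
    """Long-format pre/post panel for the assigned arrays.

    Post-treatment firing is the correlated follow-up of baseline
    (rho = ``treatment_rho``); each non-control group receives the
    treatment effect of one MEA-tested extract (its dlog10hz), so the
    effect-model stage estimates known quantities.
    """
    assigned = plan.assignment
    base = metrics.set_index("array").loc[assigned.index, "log10hz"]
    rng = child_rng(config.seed, "treatment_panel")

    mea_ext = pheno_df[pheno_df["assay"].isin(["MEA", "MEA/NI"])]
    groups = sorted(set(assigned))
    extract_of_group = {"G1": "vehicle"}
    effects = {"G1": 0.0}
    for g, (_, row) in zip(groups[1:], mea_ext.iterrows()):
        extract_of_group[g] = row["individual"]
        effects[g] = float(row["dlog10hz"])
    rows = []
    for exp in ("E1", "E2"):  # two replicate experiments with fresh
        # follow-up draws and their own intercepts
        exp_offset = float(rng.normal(0.0, 0.1))
        post = paired_followup(base.to_numpy(), config.treatment_rho, rng)
        for i, (array, group) in enumerate(assigned.items()):
            eff = effects.get(group, 0.0)
            common = {"array": f"{array}-{exp}", "experiment": exp,
                      "extract": extract_of_group.get(group, group),
                      "group": group}
            rows.append({**common, "time": "pre",
                         "log10hz": float(base.iloc[i]) + exp_offset})
            rows.append({**common, "time": "post",
                         "log10hz": float(post[i] + eff) + exp_offset})
    return pd.DataFrame(rows)
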