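# Interchange formats

All tables are plain text with a header row: CSV for spike events, TSV for
everything else. Missing LFQ entries are empty cells. The vendor's
proprietary binary recording format is out of scope; recordings enter the
pipeline as the extracted spike-event CSV below.

## Inputs

### spikes.csv
One row per detected spike event.

| column | type | meaning |
|---|---|---|
| well | str | array id (96-well plate position, e.g. `A1`) |
| electrode | int | 0-based electrode index within the array (0-7) |
| t_s | float | event timestamp, seconds from recording start |
| threshold_uV | float | crossing threshold at detection, microvolts |

### lfq.tsv
Proteins x individuals label-free quantification intensities, raw scale.
First column `protein` (row ids), remaining columns one per individual.
Empty cell = missed quantification.

### samples.tsv
| column | type | meaning |
|---|---|---|
| individual | str | individual/extract id, matching lfq.tsv columns |
| run | str | LC-MS/MS run label (batch) |
| category | str | diagnostic category: `LP-NCI`, `HP-NCI` or `AD` |

### phenotypes.tsv
| column | type | meaning |
|---|---|---|
| individual | str | individual/extract id |
| category | str | diagnostic category |
| assay | str | `MEA`, `NI`, `MEA/NI` or `NA` |
| ni_percent | float | % neurite integrity at the terminal timepoint |
| dlog10hz | float | treatment effect on firing, delta log10 Hz |

### measures.tsv
First column `individual`; one column per ELISA/MS measure (Abeta42,
Abeta42_40, oAbeta_71A1, oAbeta_1C22, pT181, pT217, tau_total, tau_N,
tau_MTBR2). Positive concentrations; rank statistics downstream are
invariant to the unit.

## Outputs

- `array_metrics.tsv`: array, n_spikes, duration_s, mfr_hz, log10hz
  (after plate-level noise exclusion; silent arrays retained with n = 0).
- `assignment.tsv`: array, group; `assignment_report.json`: achieved F,
  number of candidates, seed.
- `contrasts.tsv`: per-extract ANCOVA + Tukey post-time contrast
  (comparison, estimate, se, p_adj).
- `effects.tsv`: mixed-model estimates per extract level x time
  (level, time, estimate, se).
- `power_grid.tsv`: sample_size, effect_size, n_iter, n_sig, power.
- `normalized.tsv`: filtered, normalised, run-corrected log2 LFQ matrix.
- `de_results.tsv`: protein, group means, Welch t, p, q, significance.
- `clusters.tsv`: individual, cluster; `pca_scores.tsv`: individual, PCs.
- `screen_ni.tsv` / `screen_mea.tsv`: feature, n_used, rho, z, p, p_holm,
  rank (sorted by |rho| descending, waterfall order).
- `shared_hits.tsv`: feature, rho/p per assay, sign_concordant.
- `measure_corr.tsv`: measure, assay, n_used, rho, p.
- `manifest.json`: package version, seed, full parameter set, SHA-256 of
  every input file, elapsed time.
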