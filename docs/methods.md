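# Methods

`neuroscreen` implements the computational path from in-vitro neuronal
assays and label-free proteomics of human brain extracts to a ranked list
of neurotoxic and neuroprotective candidate proteins. This note records
the models, the defaults and why they were chosen, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Spike metrics (`mea_metrics`)

Raw multi-electrode-array voltage (12 kHz) is band-pass filtered with a
3rd-order Butterworth at 200–2500 Hz, applied forward-backward
(`sosfiltfilt`) so the filter is zero-phase: phase distortion would shift
event timestamps. The filter order is a design choice — standard for
extracellular spikes — as only the band is dictated by the acquisition
protocol. Detection is threshold crossing: an event fires where the
absolute filtered voltage first exceeds 5.5 × the RMS of a trailing 10 ms
window (grown from the start for t < 10 ms, so the estimate is causal).
Both polarities trigger. A 1 ms refractory hold-off suppresses
re-triggering; without it a single biphasic waveform yields two events.
On the filtered, zero-mean signal the RMS and the SD coincide, so the
"5.5 SD of RMS" rule has a single reading.

High-noise electrodes are removed at the event level: the crossing
thresholds of *all* events on the plate are pooled, an upper limit is set
at mean + 3 × sample SD, and events above it are dropped, in one pass
(the limit is never recomputed on the reduced set). Two consequences
worth knowing: (i) a single outlying event among ≤ 10 can never be
removed (the maximum z-score of n points is (n−1)/√n < 3 for n ≤ 10);
(ii) the rule can only remove a noise class that is a minority of pooled
events — if a fraction f of events are noise, removal requires
3√(f(1−f)) < 1−f, i.e. f < 0.1. The synthetic generator respects both
constraints (below).

Per array (8 electrodes pooled), the mean firing rate is MFR = n/s, and
the log-scale metric is log10[(n+1)/s] so silent arrays (n = 0) remain
defined and retained.

## Treatment assignment (`design_assignment`)

Active arrays are those with log10 MFR no more than 2 sample SDs below
the median, with median and SD computed on the *full* sample set before
exclusion. Assignment draws i = 10⁴ independent candidate splits of
g groups × n arrays (the assigned subset is re-drawn per candidate when
the pool exceeds g·n; duplicates across candidates are allowed), scores
each by the one-way ANOVA F of log10 MFR by group, and keeps the minimum;
ties keep the first. Zero between- and within-group variance defines
F = 0. On 8 arrays / 2 groups the probability of missing the enumerated
global minimum with 10⁴ draws is (34/35)^10⁴ < 10⁻¹²⁶.

## Effect models (`effect_models`)

Single experiments use the ANCOVA of log10 Hz on treatment group, time
and their interaction. With pre/post time labels the model is saturated,
so its coefficients are the four cell means and the residual variance is
the pooled within-cell variance. Post-hoc comparisons use Tukey's honest
significant difference over the cells via the studentized-range
distribution (Tukey–Kramer SE for unequal cell sizes); the control vs
treatment contrast at the post time is extractable by label. The
implementation is verified to 1e-6 against frozen `TukeyHSD` values from
an R session on the same data.

Multi-experiment panels use a linear mixed model with the categorical
fixed factor (extract, individual or diagnosis) crossed with time, and
nested random intercepts for whichever of individual, experiment and
array lie below the fixed factor. Nesting is encoded by composite
grouping keys (individual/experiment/array) as variance components;
estimation is REML (the estimator is a design choice — the model
structure, not the estimator, is dictated by the design). Time is
categorical throughout. A singular or non-converging fit drops the finest
variance component and retries, falling back to OLS on the cell-means
design when no random structure is estimable; dropped components are
reported in the result object rather than silently absorbed.

General linear hypothesis tests are Wald t statistics on a contrast
matrix with single-step multivariate-t familywise adjustment:
p_i = 1 − P(max_j |T_j| ≤ |t_i|) under the joint t distribution implied
by the contrast correlation. The box probability is evaluated by
quasi-Monte-Carlo (scrambled Sobol, fixed seed, 2¹⁷ points ≈ 1.3 × 10⁵;
absolute accuracy ~10⁻⁴, checked against R `multcomp::glht` to 10⁻³).
Perfectly correlated duplicate contrasts collapse to one effective
contrast, and a single effective contrast reduces exactly to the
two-sided t p-value. Holm's step-down adjustment is used for generic
p-value families.

## Power simulation (`power_simulation`)

A pool of untreated baseline recordings (default: 1272 synthetic arrays,
matching the design's pool size) gives the t₀ vector A. The follow-up is
B = ρA + A⊥√(1−ρ²), where A⊥ is the residual of regressing an
independent normal draw on A, **rescaled to the sample SD of A**, so the
sample correlation cor(A, B) equals ρ exactly (to ~10⁻¹⁶) rather than in
expectation; ρ defaults to 0.8, the estimated between-recording
correlation. The paired pool is built once per grid run.

Each simulated treatment draws 2n distinct arrays without replacement
(control and treatment disjoint, as in a real plate), subtracts the
effect size from the treatment group's t₁ values (treatments in this
system reduce firing; the grid reports |effect|), fits the saturated
group × time ANCOVA and extracts the Tukey-adjusted p of the
control-vs-treatment comparison at t₁. Power per (sample size, effect
size) cell is the fraction of iterations with p < 0.05. Because the
model is saturated, "adjusted p < α" is equivalent to q > q_crit(α; 4,
4n−4) on the studentized-range scale; the implementation vectorises that
closed form over iterations and the test suite asserts its equivalence
with the literal ANCOVA + Tukey route on random draws.

Two properties of this procedure deserve emphasis, both verified
empirically (and independently in R with `aov`/`TukeyHSD`):

- **The extracted contrast is conservative.** Tukey calibrates the
  familywise error over all 6 pairwise cell comparisons; the type-I rate
  of the single extracted contrast at nominal α = 0.05 is ≈ 0.011, not
  0.05. Power numbers from this design are correspondingly conservative.
- **ρ has only a weak effect on power.** Since B is rescaled so
  var(B) = var(A), the factorial test (time as a factor, not a baseline
  covariate) barely exploits the pairing; moving ρ from 0.5 to 0.99
  raises power at (n = 8, effect = 0.3) by only ≈ 0.014. The direction
  is real and tested, but detecting it needs thousands of iterations.

The full grid (sizes 3–16 × effects 0.1–2.0 step 0.1 × 5000 iterations)
totals exactly 1.4 million simulated treatments; the default desk-scale
profile runs 200 iterations/cell (~56k treatments, a few seconds) with a
`--full` flag for the 5000-iteration grid.

## Proteome preparation (`proteome_prep`)

The pipeline over the proteins × individuals LFQ matrix is staged and
order-enforced (raw → normalized → corrected → filtered → imputed);
calling a stage out of order is a contract error, not a warning.

*Normalisation.* Variance stabilisation is implemented as a per-sample
affine calibration (each sample's observed intensities are median/MAD
matched to the cross-sample reference) followed by the generalised log
glog2(y) = log2(y + √(y² + c²)) − 1 with c set to the reference MAD.
This is a deterministic transform with the defining properties of the
published VSN approach — measurement variance approximately independent
of intensity, cross-sample comparability, ≈ log2 at high abundance — and
those properties, not numerical identity with any particular
implementation, are what the tests assert. Values are reported on the
log2 scale directly; applying a second literal log2 after the glog would
break sign and is not done.

*Run correction.* Per protein, the log2 values are regressed on the
LC-MS run indicator over non-missing entries (equivalently, per-run means
are subtracted) and re-centred on the protein's grand mean, which is
preserved to < 10⁻⁹. Proteins observed in one run pass through up to
re-centring.

*Filter and imputation.* Proteins missing in more than 4 samples are
dropped (with the cohort's 43 individuals this is the ≥ 39-of-43
quantification rule); retained values are never altered. Protein-wise
mean imputation is applied only for clustering and PCA — the orientation
choice (protein means, not individual means) is deliberate, since
imputing an individual's average over all proteins into one protein has
no meaning. Normalisation, run correction, differential expression and
the correlation screen are all complete-case.

*Inference and structure.* Differential expression between two
categories is a per-protein Welch t-test (≥ 3 observed values per group)
with the two-stage linear step-up FDR (Benjamini–Krieger–Yekutieli; note
its first stage tests at α/(1+α), so a single-protein family has
q = 1.05·p). Individuals are clustered by complete-linkage agglomeration
on d = 1 − Spearman ρ between protein vectors (invariant to any strictly
monotone per-individual transform; verified against a naive O(n³)
oracle to 10⁻¹²), cluster-vs-diagnosis association is Pearson's
chi-squared without continuity correction, and PCA is protein-centred
over individuals.

## Phenotype screen (`phenotype_screen`)

Neurite-length series are normalised to the mean of the first 6 h of
imaging (reported in %; terminal value read at 72 h by default). For
each protein, Spearman's ρ (average-rank ties — the conventional
definition) is computed against the assay metric over the complete-case
overlap, and converted to z = √((n−3)/1.06) · arctanh(ρ) with n the
*per-feature* complete-case count; the 1.06 factor is the standard
variance inflation for Spearman's ρ under normality, applied exactly as
stated. Two-sided normal p-values follow; |ρ| = 1 saturates to an
infinite-z sentinel with p = 0. Holm adjustment runs across the protein
family and features are ranked by |ρ| (waterfall order). The normal
approximation is validated against a 10⁴-permutation null at n = 20
(agreement within 0.02 near p = 0.05). A negative ρ (more protein, more
deficit) is a neurotoxic association; positive is protective. Shared
hits are the features with unadjusted p < 0.05 in both assays, with a
sign-concordance flag. The Aβ/tau measure panel goes through the same
ρ/z machinery per (measure, assay) pair on complete cases.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of (config, seed); the global seed
expands to per-component child streams by hashing a component label into
a `SeedSequence` spawn key. Defaults encode the study conditions: 43
individuals (14 LP-NCI / 14 HP-NCI / 15 AD by severity tertiles with 10%
label noise), 1841 proteins over 2 LC-MS runs, 19 MEA / 27 NI / 4
dual-assay individuals, 48 arrays × 8 electrodes × 30-min recordings,
ρ = 0.8.

*Spike trains* are homogeneous Poisson per electrode — the downstream
metrics use only counts, so richer dynamics (bursting, synchrony) would
add nothing the pipeline can see. Array-level log10 MFR is drawn
Normal(−0.5, 0.5) (the real distribution across untreated arrays is not
published; these are configurable placeholders). Noise electrodes
(fraction 0.02) emit spurious events at 0.1 Hz with thresholds +15 bulk
SDs above the bulk: parameters chosen so noise events are a clear but
*minority* class, which the mean+3SD rule can provably remove (see the
feasibility constraint above).

*LFQ matrix*: lognormal base abundances (log2 ~ Normal(20, 2)), additive
per-run log2 offsets (SD 0.5), and missing-not-at-random entries with
logistic probability in −log2 abundance. The logistic midpoint default
(2.9 SDs below the mean) calibrates overall missingness to ≈ 1%,
matching the cohort's printed imputation accounting (646 of 79,163
observations ≈ 0.8%).

*Planted proteins and phenotypes.* Each planted protein has a latent
level per individual; the assay effects are coefficient-weighted sums of
the latents of the proteins scoped to that assay plus Gaussian noise,
mapped to the observed scales by strictly monotone logistic maps (NI in
(0, 110]%, firing effect in [−2, 0.5] log10 Hz — monotone maps avoid
clipping ties that would corrupt rank statistics). Dual-assay planted
proteins load (default 0.6) on a shared severity axis with sign opposite
to their coefficient, mirroring the observation that toxic (lysosomal)
and protective (actin-regulatory) factors anticorrelate across the
pathology spectrum; this is also what makes *two* dual hits jointly
recoverable at n = 19 — with independent latents, two equal-strength
dual proteins cap each true ρ at 1/√2. The default dual-toxic
coefficient (−2.2, effective true ρ ≈ 0.87 with both assays) is set by a
design power analysis: with 1841 proteins and n = 27, the null maximum
|ρ| reaches ≈ 0.73, so a hit meant to rank first across seeds — as the
study's validated hit did — must sit above that. Planted proteins are
pinned at the mean base abundance (reliably quantified, as the study's
validated hit was), so they never fall to the missingness filter.

*What passing tests show.* Recovery tests establish that the pipeline
finds what the generative model plants at study scale — correct
plumbing, calibrated nulls, adequate power under the stated conditions.
They do not establish robustness to features real data have and the
generator lacks: bursting and network structure in spike trains,
peptide-level quantification artefacts, correlated protein modules
beyond the planted axis, non-logistic missingness, or assay drift.
Differential expression on default synthetic data is near-null by
design (categories differ only through the five planted proteins, which
cannot clear an FDR over 1841 tests); DE sensitivity/FDR is instead
tested on matrices with explicit planted shifts.

## Problem sizes in the default runs

The analysis drivers and the test suite run at the study's natural scale
where that is cheap (1841 × 43 proteomics, 1272-array power pool) and at
reduced scale where iteration counts dominate: the power grid defaults
to 200 iterations/cell (the full 5000 behind `--full`), Monte-Carlo
sweeps use 20–500 seeds per property, and the permutation oracle uses
10⁴ permutations. Each choice is stated next to the test or driver it
belongs to.

## Known limitations

- The mixed model emulates the nested random-effects structure with
  composite grouping keys under `statsmodels` MixedLM; degenerate
  designs fall back along a documented path rather than failing.
- The VSN step is a faithful-in-spirit deterministic reimplementation,
  not the published reference implementation.
- The Tukey-extracted contrast is familywise-calibrated, so "power at
  α = 0.05" from this design is conservative (effective per-contrast
  α ≈ 0.011); this is a property of the published procedure itself.
- Spearman p-values use the modified Fisher normal approximation
  everywhere; at very small n (< ~10) exact permutation would be
  preferable.
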