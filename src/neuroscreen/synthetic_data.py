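"""Synthetic inputs with the statistical structure the analysis assumes.

Emulates the three data streams the pipeline consumes:

* spike-event tables from multi-electrode arrays (MEAs): homogeneous
  Poisson trains with lognormal per-array rates, per-event crossing
  thresholds, and an optional minority of "high-noise" electrodes whose
  thresholds sit far above the bulk;
* a label-free quantification (LFQ) protein-abundance matrix with per-run
  offsets, abundance-dependent missingness, and a small set of planted
  proteins linearly coupled to the phenotypes;
* per-individual phenotype vectors (% neurite integrity and the treatment
  effect on log10 firing) for three diagnostic categories.

Every generator is a pure function of its config: identical (config, seed)
pairs give bit-identical outputs. A single global seed expands to
per-component child seeds through :func:`child_rng`, which hashes a string
label into a ``numpy`` ``SeedSequence`` spawn key.

Truth objects record the planted ground truth (true rates, noise
electrodes, planted coefficients, run offsets, latent phenotype values) so
parameter-recovery tests can compute every expected value without
re-simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import InvalidConfigError

CATEGORIES = ("LP-NCI", "HP-NCI", "AD")


@dataclass(frozen=True)
class PlantedProtein:
    """A protein whose abundance is linearly coupled to phenotype.

    ``coeff`` is the phenotype-side coefficient: negative means higher
    abundance goes with a stronger (more negative) assay effect, i.e. a
    neurotoxic association; positive is protective. ``assay`` scopes the
    coupling to one assay or to both.
    """

    index: int
    coeff: float
    assay: str = "both"  # "NI", "MEA" or "both"

    def affects(self, assay: str) -> bool:
        return self.assay == "both" or self.assay == assay


def default_planted() -> tuple[PlantedProtein, ...]:
    """The default planted set: one strong dual-assay toxic protein (the
    GM2A archetype), one dual protective protein, and three single-assay
    proteins."""
    return (
        PlantedProtein(0, -2.2, "both"),
        PlantedProtein(1, 0.8, "both"),
        PlantedProtein(2, -0.5, "NI"),
        PlantedProtein(3, -0.5, "MEA"),
        PlantedProtein(4, 0.5, "NI"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for every generator.

    The defaults mirror the study design: 43 individuals in three
    diagnostic categories, 1841 quantified proteins over 2 LC-MS/MS runs,
    8-electrode arrays recorded for 30 minutes, and a between-recording
    correlation of rho = 0.8 on the log10 firing scale.
    """

    seed: int = 0
    # --- MEA arm ---
    n_arrays: int = 48
    n_electrodes_per_array: int = 8
    duration_s: float = 1800.0
    baseline_log10hz_mean: float = -0.5
    baseline_log10hz_sd: float = 0.5
    rho: float = 0.8
    threshold_mean_uv: float = 20.0
    threshold_sd_uv: float = 2.0
    threshold_jitter_uv: float = 0.5
    noise_electrode_fraction: float = 0.02
    noise_threshold_offset_sd: float = 15.0
    noise_event_rate_hz: float = 0.1
    # --- proteomics arm ---
    n_individuals: int = 43
    n_proteins: int = 1841
    n_runs: int = 2
    run_offset_sd: float = 0.5
    missing_rate_slope: float = 1.0
    missing_mid_sd: float = 2.9  # logistic midpoint, SDs below the mean log2
    lfq_base_log2_mean: float = 20.0
    lfq_base_log2_sd: float = 2.0
    lfq_noise_sd: float = 0.3
    planted_protein_scale: float = 1.5
    planted_proteins: tuple[PlantedProtein, ...] = field(
        default_factory=default_planted
    )
    # --- phenotype arm ---
    planted_severity_loading: float = 0.6  # dual-assay planted proteins
    # share a common severity axis with this loading (toxic and protective
    # factors anticorrelate across the pathology spectrum)
    pheno_noise_sd: float = 0.3
    n_mea: int | None = None  # individuals tested on MEAs (default ~19/43)
    n_ni: int | None = None  # individuals tested for neurite integrity (~27/43)
    n_overlap: int | None = None  # tested in both assays (~4/43)
    category_label_noise: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidConfigError(f"rho must be in [0, 1], got {self.rho}")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        for name in ("n_arrays", "n_electrodes_per_array", "n_individuals",
                     "n_proteins", "n_runs"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be a positive count")
        if not 0.0 <= self.noise_electrode_fraction < 1.0:
            raise InvalidConfigError("noise_electrode_fraction must be in [0, 1)")
        for p in self.planted_proteins:
            if not 0 <= p.index < self.n_proteins:
                raise InvalidConfigError(
                    f"planted protein index {p.index} out of range")
            if p.assay not in ("NI", "MEA", "both"):
                raise InvalidConfigError(f"unknown assay scope {p.assay!r}")

    def assay_counts(self) -> tuple[int, int, int]:
        """(n_mea, n_ni, n_overlap) scaled from the study's 19/27/4 of 43."""
        n = self.n_individuals
        n_mea = self.n_mea if self.n_mea is not None else round(19 / 43 * n)
        n_ni = self.n_ni if self.n_ni is not None else round(27 / 43 * n)
        n_overlap = (self.n_overlap if self.n_overlap is not None
                     else min(round(4 / 43 * n), n_mea, n_ni))
        if n_mea + n_ni - n_overlap > n:
            raise InvalidConfigError("assay membership exceeds cohort size")
        return n_mea, n_ni, n_overlap


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component generator: the label is hashed (CRC-32)
    into the spawn key of a ``SeedSequence`` rooted at the global seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(label.encode()),))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# spike-event tables
# ---------------------------------------------------------------------------

@dataclass
class SpikeTruth:
    """Ground truth for a generated spike table."""

    array_rate_hz: np.ndarray  # biological rate per array (pooled electrodes)
    electrode_rate_hz: np.ndarray  # (n_arrays, n_electrodes)
    noise_electrodes: pd.DataFrame  # columns: well, electrode
    duration_s: float


def _well_label(i: int) -> str:
    # 96-well plate labelling A1..H12, recycled beyond 96 arrays
    row = "ABCDEFGH"[(i % 96) // 12]
    return f"{row}{(i % 96) % 12 + 1}{'' if i < 96 else '_' + str(i // 96)}"


def gen_spike_table(config: SimConfig) -> tuple[pd.DataFrame, SpikeTruth]:
    """Homogeneous Poisson spike trains for ``n_arrays`` arrays.

    Per array the pooled log10 mean firing rate is drawn
    Normal(baseline_log10hz_mean, baseline_log10hz_sd); the rate is split
    evenly over that array's non-noise electrodes. Noise electrodes carry no
    biological signal: they emit spurious events at ``noise_event_rate_hz``
    whose crossing thresholds sit ``noise_threshold_offset_sd`` bulk SDs
    above the bulk threshold mean, which is what the plate-level mean+3SD
    exclusion removes downstream.

    Returns the event table (columns ``well, electrode, t_s, threshold_uV``)
    and a :class:`SpikeTruth`.
    """
    rng = child_rng(config.seed, "spike_table")
    n_arr, n_el = config.n_arrays, config.n_electrodes_per_array
    dur = config.duration_s

    log10_rate = rng.normal(config.baseline_log10hz_mean,
                            config.baseline_log10hz_sd, size=n_arr)
    array_rate = 10.0 ** log10_rate
    noise_mask = rng.random((n_arr, n_el)) < config.noise_electrode_fraction
    # an array whose electrodes are all noise keeps its rate on none of them
    clean_counts = np.maximum((~noise_mask).sum(axis=1), 1)
    electrode_rate = np.where(noise_mask, 0.0,
                              (array_rate / clean_counts)[:, None])

    noise_thresh_mean = (config.threshold_mean_uv
                         + config.noise_threshold_offset_sd * config.threshold_sd_uv)

    rows: list[pd.DataFrame] = []
    for a in range(n_arr):
        well = _well_label(a)
        for e in range(n_el):
            bio_rate = electrode_rate[a, e]
            base = noise_thresh_mean if noise_mask[a, e] else None
            rate = config.noise_event_rate_hz if noise_mask[a, e] else bio_rate
            n_events = rng.poisson(rate * dur)
            if n_events == 0:
                continue
            t = np.sort(rng.uniform(0.0, dur, size=n_events))
            centre = base if base is not None else rng.normal(
                config.threshold_mean_uv, config.threshold_sd_uv)
            thr = centre + rng.normal(0.0, config.threshold_jitter_uv,
                                      size=n_events)
            rows.append(pd.DataFrame({
                "well": well, "electrode": e, "t_s": t,
                "threshold_uV": np.maximum(thr, 1e-6),
            }))
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["well", "electrode", "t_s", "threshold_uV"])
        table = table.astype({"well": str, "electrode": int,
                              "t_s": float, "threshold_uV": float})

    arr_idx, el_idx = np.nonzero(noise_mask)
    noise_df = pd.DataFrame({
        "well": [_well_label(a) for a in arr_idx], "electrode": el_idx,
    })
    truth = SpikeTruth(array_rate_hz=array_rate, electrode_rate_hz=electrode_rate,
                       noise_electrodes=noise_df, duration_s=dur)
    return table, truth


def gen_voltage_trace(duration_s: float, sampling_hz: float,
                      spike_times_s: np.ndarray, amplitude_uv: float,
                      noise_sd_uv: float, seed: int) -> np.ndarray:
    """A Gaussian-noise voltage trace with biphasic pulses injected at the
    given times; used to exercise threshold-crossing spike detection."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_hz))
    trace = rng.normal(0.0, noise_sd_uv, size=n)
    # biphasic waveform ~1 ms long: negative lobe then positive lobe
    w = int(round(sampling_hz / 1000.0))
    t = np.arange(2 * w)
    wave = np.sin(np.pi * t / w) * np.hanning(2 * w)
    wave = wave / np.max(np.abs(wave)) * amplitude_uv
    for ts in np.asarray(spike_times_s, dtype=float):
        i = int(round(ts * sampling_hz))
        j = min(i + 2 * w, n)
        trace[i:j] -= wave[: j - i]
    return trace


# ---------------------------------------------------------------------------
# paired baseline / follow-up firing
# ---------------------------------------------------------------------------

def paired_followup(a: np.ndarray, rho: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Follow-up vector B = rho*A + A_perp*sqrt(1 - rho^2).

    ``A_perp`` is the residual of regressing an independent standard-normal
    draw on A, rescaled to the sample SD of A so that the sample correlation
    cor(A, B) equals rho exactly (to floating-point rounding) rather than
    only in expectation.
    """
    a = np.asarray(a, dtype=float)
    if not 0.0 <= rho <= 1.0:
        raise InvalidConfigError(f"rho must be in [0, 1], got {rho}")
    if a.size < 4:
        raise InvalidConfigError("need at least 4 arrays to build residuals")
    w = rng.standard_normal(a.size)
    x = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(x, w, rcond=None)
    resid = w - x @ beta
    sd_r = resid.std(ddof=1)
    if sd_r > 0:
        resid = resid * (a.std(ddof=1) / sd_r)
    return rho * a + resid * np.sqrt(1.0 - rho ** 2)


def gen_paired_log10hz(config: SimConfig,
                       n: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Baseline/follow-up log10 firing pair (A, B) with cor(A, B) = rho."""
    rng = child_rng(config.seed, "paired_log10hz")
    n = config.n_arrays if n is None else n
    a = rng.normal(config.baseline_log10hz_mean, config.baseline_log10hz_sd,
                   size=n)
    b = paired_followup(a, config.rho, rng)
    return a, b


# ---------------------------------------------------------------------------
# phenotypes and the LFQ matrix (coherent joint model)
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTruth:
    """Latent phenotype structure shared by the LFQ and phenotype generators."""

    individuals: list[str]
    planted_latent: np.ndarray  # (n_planted, n_individuals) latent levels
    ni_raw: np.ndarray  # latent NI effect scale (before the % mapping)
    mea_raw: np.ndarray  # latent MEA effect scale (before the dlog10hz mapping)
    severity: np.ndarray  # higher = more neurotoxic burden


def _individual_ids(n: int) -> list[str]:
    return [f"IND{i + 1:03d}" for i in range(n)]


def _latent_phenotypes(config: SimConfig) -> PhenotypeTruth:
    """Latents shared between gen_lfq_matrix and gen_phenotypes.

    Each planted protein has one standard-normal latent level per
    individual; an assay's latent effect is the coefficient-weighted sum of
    the latents of the proteins scoped to that assay, plus Gaussian noise.
    With no planted proteins and no noise the phenotypes are constant.
    """
    rng = child_rng(config.seed, "phenotype_latents")
    n = config.n_individuals
    planted = config.planted_proteins
    sev_axis = rng.standard_normal(n)
    eps = (rng.standard_normal((len(planted), n)) if planted
           else np.zeros((0, n)))
    w = config.planted_severity_loading
    lat = np.empty_like(eps)
    for k, p in enumerate(planted):
        if p.assay == "both" and w > 0:
            # toxic duals rise, protective duals fall along the shared axis
            lat[k] = (-np.sign(p.coeff) * w * sev_axis
                      + np.sqrt(1.0 - w ** 2) * eps[k])
        else:
            lat[k] = eps[k]
    ni_raw = np.zeros(n)
    mea_raw = np.zeros(n)
    for k, p in enumerate(planted):
        if p.affects("NI"):
            ni_raw += p.coeff * lat[k]
        if p.affects("MEA"):
            mea_raw += p.coeff * lat[k]
    ni_raw = ni_raw + rng.normal(0.0, config.pheno_noise_sd, size=n)
    mea_raw = mea_raw + rng.normal(0.0, config.pheno_noise_sd, size=n)
    severity = -(ni_raw + mea_raw) / 2.0
    return PhenotypeTruth(individuals=_individual_ids(n), planted_latent=lat,
                          ni_raw=ni_raw, mea_raw=mea_raw, severity=severity)


@dataclass
class LfqTruth:
    """Ground truth for a generated LFQ matrix."""

    base_log2: np.ndarray  # per-protein base abundance, log2
    run_offsets: np.ndarray  # per-run additive offset, log2
    run_of_individual: pd.Series
    planted: tuple[PlantedProtein, ...]
    phenotypes: PhenotypeTruth


def gen_lfq_matrix(config: SimConfig):
    """Proteins x individuals LFQ abundance table on the raw scale.

    Base abundances are lognormal (normal on log2). Planted proteins add
    ``planted_protein_scale`` log2 units per unit of their latent level.
    Each individual belongs to one LC-MS run carrying an additive log2
    offset. Missingness is logistic in minus log2 abundance with slope
    ``missing_rate_slope``: low-abundance entries are missed more often
    (missing-not-at-random), matching label-free proteomics practice.

    Returns an :class:`~neuroscreen.proteome_prep.LfqMatrix` (stage "raw")
    and an :class:`LfqTruth`.
    """
    from .proteome_prep import LfqMatrix  # deferred: avoids import cycle

    rng = child_rng(config.seed, "lfq_matrix")
    pheno = _latent_phenotypes(config)
    n_p, n_i = config.n_proteins, config.n_individuals

    base = rng.normal(config.lfq_base_log2_mean, config.lfq_base_log2_sd,
                      size=n_p)
    # planted proteins are reliably quantified: pin them at the mean base
    # abundance so they never fall into the high-missingness tail
    for p in config.planted_proteins:
        base[p.index] = config.lfq_base_log2_mean
    log2 = base[:, None] + rng.normal(0.0, config.lfq_noise_sd, size=(n_p, n_i))
    for k, p in enumerate(config.planted_proteins):
        log2[p.index] += config.planted_protein_scale * pheno.planted_latent[k]

    run_offsets = (rng.normal(0.0, config.run_offset_sd, size=config.n_runs)
                   if config.run_offset_sd > 0 else np.zeros(config.n_runs))
    run_idx = rng.integers(0, config.n_runs, size=n_i)
    log2 = log2 + run_offsets[run_idx][None, :]

    if config.missing_rate_slope > 0:
        mid = (config.lfq_base_log2_mean
               - config.missing_mid_sd * config.lfq_base_log2_sd)
        p_miss = expit(config.missing_rate_slope * (mid - log2))
        missing = rng.random((n_p, n_i)) < p_miss
        # keep at least one observation per protein so means stay defined
        all_missing = missing.all(axis=1)
        missing[all_missing, 0] = False
    else:
        missing = np.zeros((n_p, n_i), dtype=bool)

    individuals = pheno.individuals
    proteins = [f"PROT{i + 1:05d}" for i in range(n_p)]
    values = pd.DataFrame(2.0 ** log2, index=proteins, columns=individuals)
    values = values.mask(pd.DataFrame(missing, index=proteins,
                                      columns=individuals))
    runs = pd.Series([f"run{r + 1}" for r in run_idx], index=individuals,
                     name="run")
    categories = gen_phenotypes(config)[0].set_index("individual")["category"]
    matrix = LfqMatrix(values=values, runs=runs,
                       categories=categories.reindex(individuals),
                       stage="raw")
    truth = LfqTruth(base_log2=base, run_offsets=run_offsets,
                     run_of_individual=runs, planted=config.planted_proteins,
                     phenotypes=pheno)
    return matrix, truth


def gen_phenotypes(config: SimConfig) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Per-individual phenotype table emulating the cohort layout.

    Columns: ``individual, category, assay, ni_percent, dlog10hz``. The
    assay column is "MEA", "NI", "MEA/NI" or "NA", with counts scaled from
    the study's 19 MEA / 27 NI / 4 overlap of 43. Latent effects map to the
    observed scales through strictly monotone logistic maps, so neurite
    integrity stays in (0, 110]% and the firing effect in [-2, 0.5]
    log10 Hz without clipping ties.
    """
    if config.n_individuals < 3:
        raise InvalidConfigError("need at least 3 individuals for 3 categories")
    rng = child_rng(config.seed, "phenotypes")
    pheno = _latent_phenotypes(config)
    n = config.n_individuals

    ni = 110.0 * expit(0.8 * pheno.ni_raw + 1.8)
    dlog = -2.0 + 2.5 * expit(0.9 * pheno.mea_raw + 1.6)

    # category by tertiles of severity, with label noise
    order = np.argsort(np.argsort(pheno.severity, kind="stable"), kind="stable")
    tert = np.minimum(order * 3 // n, 2)
    flip = rng.random(n) < config.category_label_noise
    tert = np.where(flip, rng.integers(0, 3, size=n), tert)
    category = np.asarray(CATEGORIES)[tert]

    n_mea, n_ni, n_overlap = config.assay_counts()
    assay = np.array(["NA"] * n, dtype=object)
    perm = rng.permutation(n)
    both = perm[:n_overlap]
    mea_only = perm[n_overlap:n_overlap + (n_mea - n_overlap)]
    ni_only = perm[n_overlap + (n_mea - n_overlap):
                   n_overlap + (n_mea - n_overlap) + (n_ni - n_overlap)]
    assay[both] = "MEA/NI"
    assay[mea_only] = "MEA"
    assay[ni_only] = "NI"

    table = pd.DataFrame({
        "individual": pheno.individuals,
        "category": category,
        "assay": assay,
        "ni_percent": ni,
        "dlog10hz": dlog,
    })
    return table, pheno


MEASURE_COLUMNS = ("Abeta42", "Abeta42_40", "oAbeta_71A1", "oAbeta_1C22",
                   "pT181", "pT217", "tau_total", "tau_N", "tau_MTBR2")


def gen_measures(config: SimConfig,
                 coupling: float = 0.5) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Per-individual Abeta/tau ELISA-style measure table.

    Each measure loads on the shared severity latent with strength
    ``coupling`` (plus unit noise), emulating the observation that amyloid
    and tau species track assay effect size only partially. Values are
    reported on a positive lognormal-like scale (pg/mL-flavoured), which
    rank-based correlation downstream is invariant to.
    """
    rng = child_rng(config.seed, "measures")
    pheno = _latent_phenotypes(config)
    n = config.n_individuals
    sev = pheno.severity
    sd = sev.std() if sev.std() > 0 else 1.0
    data = {}
    for m in MEASURE_COLUMNS:
        latent = coupling * sev / sd + rng.standard_normal(n)
        data[m] = 200.0 * np.exp(0.5 * latent)
    table = pd.DataFrame(data, index=pheno.individuals)
    table.index.name = "individual"
    return table, pheno
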