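"""Protein-phenotype correlation screen with the modified Fisher transform.

Each protein's normalised abundance across individuals is correlated
(Spearman rho, average-rank ties) with the assay effect size — % neurite
integrity at the terminal imaging timepoint, or the treatment effect on
log10 firing. The rho is converted to a z-score by the Spearman-adapted
Fisher transformation

    z = sqrt((n - 3) / 1.06) * arctanh(rho)

(the 1.06 factor is the standard variance inflation of Spearman's rho
under normality), giving a two-sided normal p-value; Holm adjustment runs
across the protein family, and proteins are ranked by |rho| (waterfall
order). A negative rho against either assay means higher abundance goes
with a stronger deficit — a neurotoxic association; positive is
protective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effect_models import holm_adjust
from .exceptions import ContractError, InvalidInputError
from .proteome_prep import LfqMatrix


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-individual assay metric values for one assay."""

    values: pd.Series  # index: individual ids
    assay: str  # "NI" or "MEA"

    def __post_init__(self) -> None:
        if self.values.isna().any():
            raise InvalidInputError("phenotype values must not be missing")
        if self.values.index.has_duplicates:
            raise InvalidInputError("duplicate individual ids in phenotype")


# ---------------------------------------------------------------------------
# neurite-integrity normalisation
# ---------------------------------------------------------------------------

def normalize_neurite(series: np.ndarray, timestamps_h: np.ndarray,
                      baseline_h: float = 6.0, terminal_h: float = 72.0
                      ) -> tuple[np.ndarray, float]:
    """Normalise total neurite length to the first hours of imaging.

    Each value is divided by the mean of the values at t <= ``baseline_h``
    and reported in percent; the terminal neurite-integrity value is read
    at the timepoint closest to ``terminal_h``.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(timestamps_h, dtype=float)
    if series.shape != t.shape:
        raise InvalidInputError("series and timestamps differ in length")
    base = series[t <= baseline_h]
    if base.size < 1:
        raise ContractError(f"no timepoints within the first {baseline_h} h")
    norm = series / base.mean() * 100.0
    terminal = float(norm[np.argmin(np.abs(t - terminal_h))])
    return norm, terminal


# ---------------------------------------------------------------------------
# modified Fisher transformation
# ---------------------------------------------------------------------------

def fisher_z(rho: float, n: int) -> tuple[float, float]:
    """z = sqrt((n - 3)/1.06) * arctanh(rho) and its two-sided normal p.

    |rho| = 1 returns a signed infinite z with p = 0 (a monotone-perfect
    association saturates the transform).
    """
    if n < 4:
        raise ContractError(f"Fisher transform needs n >= 4, got {n}")
    if not -1.0 <= rho <= 1.0:
        raise InvalidInputError(f"rho must be in [-1, 1], got {rho}")
    if abs(rho) == 1.0:
        return float(np.sign(rho) * np.inf), 0.0
    z = float(np.sqrt((n - 3) / 1.06) * np.arctanh(rho))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenRow:
    """One protein's association with one assay."""

    feature: str
    n_used: int
    rho: float
    z: float
    p: float
    p_holm: float
    rank: int


def screen(matrix: LfqMatrix, phenotype: PhenotypeVector) -> pd.DataFrame:
    """Spearman correlation of every protein with the assay effect size.

    Per protein the individuals present in both the matrix and the
    phenotype with an observed abundance are used (complete-case n);
    ties get average ranks. Returns a frame sorted by |rho| descending
    (waterfall order) with columns feature, n_used, rho, z, p, p_holm,
    rank. Proteins constant over the overlap are skipped with a warning.
    """
    common = [c for c in matrix.values.columns if c in phenotype.values.index]
    if len(common) < 4:
        raise InvalidInputError(
            f"only {len(common)} individuals overlap between matrix and "
            "phenotype; need >= 4")
    sub = matrix.values[common]
    pheno = phenotype.values.reindex(common).to_numpy(dtype=float)

    rows = []
    skipped = []
    vals = sub.to_numpy(dtype=float)
    for i, feature in enumerate(sub.index):
        x = vals[i]
        obs = ~np.isnan(x)
        n_used = int(obs.sum())
        if n_used < 4:
            skipped.append((feature, "fewer than 4 complete cases"))
            continue
        xi, yi = x[obs], pheno[obs]
        if np.all(xi == xi[0]) or np.all(yi == yi[0]):
            skipped.append((feature, "constant over the overlap"))
            continue
        rho = float(stats.spearmanr(xi, yi).statistic)
        z, p = fisher_z(rho, n_used)
        rows.append({"feature": feature, "n_used": n_used, "rho": rho,
                     "z": z, "p": p})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} features "
                      f"(e.g. {skipped[0][0]!r}: {skipped[0][1]})",
                      stacklevel=2)
    if not rows:
        return pd.DataFrame(columns=["feature", "n_used", "rho", "z", "p",
                                     "p_holm", "rank"])
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    out = out.sort_values("rho", key=lambda s: s.abs(), ascending=False,
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def shared_hits(results_ni: pd.DataFrame, results_mea: pd.DataFrame,
                p_threshold: float = 0.05) -> pd.DataFrame:
    """Features with unadjusted p < threshold in both assays.

    Inner join on feature id; reports both correlations and whether their
    signs agree (a concordant neurotoxic or protective association).
    """
    cols = ["feature", "rho", "p"]
    for frame in (results_ni, results_mea):
        if not set(cols) <= set(frame.columns):
            raise InvalidInputError("screen results need feature/rho/p columns")
    ni = results_ni.loc[results_ni["p"] < p_threshold, cols]
    mea = results_mea.loc[results_mea["p"] < p_threshold, cols]
    merged = ni.merge(mea, on="feature", suffixes=("_ni", "_mea"))
    if merged.empty and not (set(results_ni["feature"])
                             & set(results_mea["feature"])):
        warnings.warn("screen results share no feature ids", stacklevel=2)
    merged["sign_concordant"] = (np.sign(merged["rho_ni"])
                                 == np.sign(merged["rho_mea"]))
    order = (merged["rho_ni"].abs() + merged["rho_mea"].abs())
    return (merged.assign(_o=order).sort_values("_o", ascending=False)
            .drop(columns="_o").reset_index(drop=True))


def measure_correlations(measures: pd.DataFrame,
                         phenotypes: dict[str, PhenotypeVector],
                         min_n: int = 4) -> pd.DataFrame:
    """Spearman rho / Fisher-z p per (measure, assay) pair.

    ``measures`` is individuals x measures (e.g. the Abeta and tau ELISA
    panel); complete cases per pair. Pairs with fewer than ``min_n``
    complete cases are reported with NaN statistics rather than dropped.
    """
    rows = []
    for measure in measures.columns:
        for assay, pheno in phenotypes.items():
            common = [i for i in measures.index
                      if i in pheno.values.index
                      and not pd.isna(measures.loc[i, measure])]
            if len(common) < min_n:
                rows.append({"measure": measure, "assay": assay,
                             "n_used": len(common), "rho": np.nan,
                             "p": np.nan})
                continue
            x = measures.loc[common, measure].to_numpy(dtype=float)
            y = pheno.values.reindex(common).to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append({"measure": measure, "assay": assay,
                             "n_used": len(common), "rho": np.nan,
                             "p": np.nan})
                continue
            rho = float(stats.spearmanr(x, y).statistic)
            _, p = fisher_z(rho, len(common))
            rows.append({"measure": measure, "assay": assay,
                         "n_used": len(common), "rho": rho, "p": p})
    return pd.DataFrame(rows)
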