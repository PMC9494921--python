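"""Normalisation, filtering, imputation and structure analysis of the LFQ
protein matrix.

The pipeline over the proteins x individuals abundance table is staged and
order-enforced: raw -> normalized (variance-stabilising transform on the
log2 scale) -> corrected (per-protein run-effect removal by linear
regression) -> filtered (drop proteins missed in >= 5 of 43 samples) ->
imputed (protein-mean imputation, used only for clustering and PCA).
Missing values are otherwise handled complete-case, as in label-free
proteomics practice. Differential expression is a per-protein Welch t-test
with two-stage step-up FDR; individuals are clustered by complete linkage
on 1 - Spearman correlation; cluster-vs-diagnosis association is a Pearson
chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError, InvalidInputError

STAGES = ("raw", "normalized", "corrected", "filtered", "imputed")


@dataclass
class LfqMatrix:
    """Proteins x individuals abundance table with run and category labels.

    ``values`` holds NaN for missing entries; ``stage`` tags where in the
    normalise -> correct -> filter -> impute chain the matrix sits, and the
    stage transitions enforce that order.
    """

    values: pd.DataFrame  # rows: proteins, columns: individuals
    runs: pd.Series  # individual -> run label
    categories: pd.Series | None = None  # individual -> diagnostic category
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ContractError(f"unknown stage {self.stage!r}")
        missing_runs = set(self.values.columns) - set(self.runs.index)
        if missing_runs:
            raise ContractError(
                f"individuals without a run label: {sorted(missing_runs)[:5]}")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the entry is missing."""
        return self.values.isna()

    def total_observations(self) -> int:
        """Individuals x proteins: the denominator of the imputed fraction."""
        return self.n_proteins * self.n_individuals

    def n_missing(self) -> int:
        return int(self.mask.to_numpy().sum())

    def _require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise ContractError(
                f"operation requires stage in {allowed}, matrix is "
                f"{self.stage!r}: the pipeline order is "
                "normalize -> correct -> filter -> impute")


def min_required_quantified(n_samples: int, max_missing: int = 4) -> int:
    """Minimum quantifications a protein must have to survive the
    missingness filter (39 of 43 with the defaults)."""
    return n_samples - max_missing


# ---------------------------------------------------------------------------
# normalisation and batch correction
# ---------------------------------------------------------------------------

def vsn_log2_normalize(matrix: LfqMatrix, min_quantified: int = 10
                       ) -> LfqMatrix:
    """Variance-stabilising normalisation reported on the log2 scale.

    Each sample's observed raw intensities are calibrated affinely
    (median/MAD matched to the cross-sample reference) and passed through
    the generalised log ``glog2(y) = log2(y + sqrt(y^2 + c^2)) - 1``,
    which is ~log2(y) at high abundance and linear near zero, so
    measurement variance becomes approximately independent of intensity.
    Rank order within each sample is preserved (positive-scale affine map
    followed by a strictly increasing transform).
    """
    matrix._require_stage("raw")
    vals = matrix.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanmin(vals) if np.isfinite(vals).any() else 0.0
    if lo < 0:
        raise InvalidInputError("raw LFQ intensities must be non-negative")

    n_obs = (~np.isnan(vals)).sum(axis=0)
    for j, col in enumerate(matrix.values.columns):
        if n_obs[j] < min_quantified:
            raise InvalidInputError(
                f"sample {col!r} has only {n_obs[j]} quantified proteins; "
                "cannot calibrate")

    med = np.nanmedian(vals, axis=0)
    mad = np.nanmedian(np.abs(vals - med[None, :]), axis=0)
    ref_med = float(np.mean(med))
    ref_mad = float(np.mean(mad))
    scale = np.where(mad > 0, ref_mad / np.where(mad > 0, mad, 1.0), 1.0)
    calibrated = (vals - med[None, :]) * scale[None, :] + ref_med

    c = ref_mad if ref_mad > 0 else 1.0
    glog2 = np.log2(calibrated + np.sqrt(calibrated ** 2 + c ** 2)) - 1.0
    out = pd.DataFrame(glog2, index=matrix.values.index,
                       columns=matrix.values.columns)
    return replace(matrix, values=out.mask(matrix.mask), stage="normalized")


def remove_run_effect(matrix: LfqMatrix) -> LfqMatrix:
    """Remove the LC-MS run effect per protein by linear regression.

    For each protein, the log2 values are regressed on the run indicator
    over non-missing entries (equivalently: per-run means are subtracted)
    and the residuals are re-centred on that protein's grand mean, which is
    therefore preserved. Proteins observed in a single run pass through
    unchanged up to that re-centring (a single level carries no run
    contrast).
    """
    matrix._require_stage("normalized")
    vals = matrix.values.to_numpy(dtype=float)
    runs = matrix.runs.reindex(matrix.values.columns)
    out = vals.copy()
    run_labels, run_idx = np.unique(runs.to_numpy(), return_inverse=True)
    obs = ~np.isnan(vals)
    grand = np.nanmean(np.where(obs, vals, np.nan), axis=1)
    if len(run_labels) > 1:
        for r in range(len(run_labels)):
            cols = run_idx == r
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                run_mean = np.nanmean(np.where(obs[:, cols], vals[:, cols],
                                               np.nan), axis=1)
            adj = np.where(np.isnan(run_mean), 0.0, run_mean - grand)
            out[:, cols] = vals[:, cols] - adj[:, None]
    frame = pd.DataFrame(out, index=matrix.values.index,
                         columns=matrix.values.columns).mask(matrix.mask)
    return replace(matrix, values=frame, stage="corrected")


def filter_missing(matrix: LfqMatrix, max_missing: int = 4) -> LfqMatrix:
    """Drop proteins missed in more than ``max_missing`` samples.

    With the study's 43 individuals and the default of 4, a retained
    protein is quantified in at least 39 samples; a protein missing in
    exactly 5 is excluded. Retained values are never altered.
    """
    matrix._require_stage("corrected", "normalized")
    n_miss = matrix.mask.sum(axis=1)
    keep = n_miss <= max_missing
    if not keep.any():
        warnings.warn("all proteins fail the missingness filter", stacklevel=2)
    return replace(matrix, values=matrix.values.loc[keep], stage="filtered")


def impute_protein_means(matrix: LfqMatrix) -> tuple[LfqMatrix, float]:
    """Replace each missing entry with that protein's mean over observed
    individuals; returns the imputed matrix and the imputed fraction.

    Protein-wise means are used (imputing an individual's mean over all
    proteins into one protein is not meaningful); used only for clustering
    and PCA, never for inference.
    """
    matrix._require_stage("filtered")
    vals = matrix.values
    if vals.isna().all(axis=1).any():
        bad = vals.index[vals.isna().all(axis=1)][0]
        raise ContractError(f"protein {bad!r} has no observed values")
    n_missing = matrix.n_missing()
    means = vals.mean(axis=1, skipna=True)
    out = vals.T.fillna(means).T  # protein-wise means broadcast over individuals
    fraction = n_missing / matrix.total_observations() if vals.size else 0.0
    return replace(matrix, values=out, stage="imputed"), fraction


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    """Per-protein Welch t-test between two diagnostic categories."""

    protein: str
    mean_a: float
    mean_b: float
    t_stat: float
    p: float
    q: float = float("nan")
    significant: bool = False


def diff_expr(matrix: LfqMatrix, pair: tuple[str, str],
              min_per_group: int = 3, fdr: float = 0.05) -> list[DeResult]:
    """Welch t-tests of every protein between two categories.

    Complete-case per protein; proteins with fewer than ``min_per_group``
    quantified values in either category are excluded. q-values come from
    the two-stage linear step-up FDR procedure, with significance at
    q < ``fdr``.
    """
    if matrix.categories is None:
        raise InvalidInputError("matrix carries no category labels")
    cat = matrix.categories.reindex(matrix.values.columns)
    cols_a = cat.index[cat == pair[0]]
    cols_b = cat.index[cat == pair[1]]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise InvalidInputError(f"no individuals in one of {pair}")

    results: list[DeResult] = []
    a_all = matrix.values[cols_a].to_numpy(dtype=float)
    b_all = matrix.values[cols_b].to_numpy(dtype=float)
    for i, prot in enumerate(matrix.values.index):
        a = a_all[i][~np.isnan(a_all[i])]
        b = b_all[i][~np.isnan(b_all[i])]
        if a.size < min_per_group or b.size < min_per_group:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        results.append(DeResult(protein=prot, mean_a=float(a.mean()),
                                mean_b=float(b.mean()), t_stat=float(t),
                                p=float(p)))
    if results:
        q = multipletests([r.p for r in results], alpha=fdr,
                          method="fdr_tsbky")[1]
        for r, qv in zip(results, q):
            r.q = float(qv)
            r.significant = bool(qv < fdr)
    return results


# ---------------------------------------------------------------------------
# clustering, diagnosis association, PCA
# ---------------------------------------------------------------------------

def spearman_distance_matrix(matrix: LfqMatrix) -> pd.DataFrame:
    """d(i, j) = 1 - Spearman rho between individuals' protein vectors."""
    vals = matrix.values.to_numpy(dtype=float)
    const = vals.std(axis=0) == 0
    if const.any():
        bad = matrix.values.columns[const][0]
        raise ContractError(
            f"individual {bad!r} has a constant protein vector; Spearman "
            "correlation is undefined")
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)
    rho = np.corrcoef(ranks.T)
    return pd.DataFrame(1.0 - rho, index=matrix.values.columns,
                        columns=matrix.values.columns)


def hcluster_individuals(matrix: LfqMatrix, k: int
                         ) -> tuple[pd.Series, np.ndarray]:
    """Complete-linkage agglomerative clustering on Spearman distance.

    Returns labels from cutting the tree into ``k`` clusters, plus the
    scipy linkage matrix (merge heights in 1 - rho units).
    """
    matrix._require_stage("imputed")
    if matrix.n_individuals < 2:
        raise InvalidInputError("need at least 2 individuals to cluster")
    dist = spearman_distance_matrix(matrix)
    condensed = squareform(dist.to_numpy(), checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.values.columns, name="cluster"), link


def cluster_category_test(labels: pd.Series, categories: pd.Series
                          ) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-squared of the cluster x category contingency table."""
    table = pd.crosstab(labels, categories.reindex(labels.index))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InvalidInputError("need >= 2 clusters and >= 2 categories")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InvalidInputError("contingency table has a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p), table


def pca_individuals(matrix: LfqMatrix, n_components: int = 10
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of individuals in protein space (protein-centred).

    Returns per-individual scores and the explained-variance fractions.
    """
    matrix._require_stage("imputed")
    x = matrix.values.to_numpy(dtype=float).T  # individuals x proteins
    n_components = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=matrix.values.columns, columns=cols),
            pca.explained_variance_ratio_)
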