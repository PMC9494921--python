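"""Treatment-effect estimation on the log10 firing scale.

Three estimation contracts cover the experimental designs in play:

* :func:`ancova_fit` — a single experiment: ordinary least squares of
  log10hz on group, time and their interaction (the saturated model whose
  coefficients are the group x time cell means);
* :func:`tukey_posthoc` — all pairwise cell comparisons through the
  studentized-range distribution (Tukey's honest significant difference,
  Tukey-Kramer standard error for unequal cell sizes);
* :func:`lme_effects` — multi-experiment panels: a linear mixed model with
  a categorical fixed-factor x time interaction and nested random
  intercepts (individual / experiment / array), fit by REML;
* :func:`glht_contrasts` — general linear hypothesis tests on a fitted
  model with single-step multivariate-t familywise adjustment;
* :func:`holm_adjust` — step-down Holm correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError, InvalidInputError

_CELL_SEP = ":"


@dataclass
class ContrastResult:
    """One estimated comparison with its familywise-adjusted p-value."""

    comparison: str
    estimate: float
    se: float
    statistic: float
    p_adj: float


@dataclass
class AncovaFit:
    """OLS fit of log10hz ~ group * time in cell-means form."""

    cells: pd.DataFrame  # columns: group, time, mean, n
    resid_df: int
    sigma2: float  # residual variance
    ols: object = field(repr=False)  # statsmodels results (coef vector etc.)

    def cell_mean(self, group: str, time: str) -> float:
        m = self.cells
        row = m[(m["group"] == group) & (m["time"] == time)]
        if row.empty:
            raise ContractError(f"unknown cell {group}{_CELL_SEP}{time}")
        return float(row["mean"].iloc[0])


def ancova_fit(data: pd.DataFrame) -> AncovaFit:
    """Fit log10hz ~ group + time + group:time by OLS.

    ``data`` needs columns ``group``, ``time`` and ``log10hz``. Every
    group x time cell must be observed; an empty cell is reported by name
    rather than silently producing a rank-deficient fit.
    """
    for col in ("group", "time", "log10hz"):
        if col not in data.columns:
            raise InvalidInputError(f"missing column {col!r}")
    groups = list(pd.unique(data["group"]))
    times = list(pd.unique(data["time"]))
    if len(groups) < 2 or len(times) < 2:
        raise InvalidInputError("need at least 2 groups and 2 time labels")
    counts = data.groupby(["group", "time"], sort=False).size()
    for g, t in itertools.product(groups, times):
        if (g, t) not in counts.index:
            raise InvalidInputError(
                f"empty cell {g}{_CELL_SEP}{t}: the interaction model is "
                "rank-deficient")

    cell = (data["group"].astype(str) + _CELL_SEP + data["time"].astype(str))
    x = pd.get_dummies(cell, dtype=float)
    ols = sm.OLS(data["log10hz"].to_numpy(dtype=float), x.to_numpy()).fit()
    means = data.groupby(["group", "time"], sort=False)["log10hz"].agg(
        ["mean", "size"]).reset_index()
    means.columns = ["group", "time", "mean", "n"]
    resid_df = int(len(data) - len(means))
    sigma2 = float(ols.ssr / resid_df) if resid_df > 0 else float("nan")
    return AncovaFit(cells=means, resid_df=resid_df, sigma2=sigma2, ols=ols)


def tukey_posthoc(fit: AncovaFit) -> list[ContrastResult]:
    """All pairwise cell comparisons via the studentized-range distribution.

    The comparison label is ``"g2:t2-g1:t1"`` so the (treatment, post) vs
    (control, post) contrast is extractable by name. Adjusted p-values use
    k = number of cells and the model's residual degrees of freedom.
    """
    cells = fit.cells
    if len(cells) < 2:
        raise InvalidInputError("need at least 2 cells for post-hoc comparisons")
    k = len(cells)
    out: list[ContrastResult] = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = cells.iloc[i], cells.iloc[j]
        diff = float(gj["mean"] - gi["mean"])
        se = float(np.sqrt(fit.sigma2 / 2.0 * (1.0 / gi["n"] + 1.0 / gj["n"])))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(stats.studentized_range.sf(q, k, fit.resid_df))
        label = (f"{gj['group']}{_CELL_SEP}{gj['time']}-"
                 f"{gi['group']}{_CELL_SEP}{gi['time']}")
        out.append(ContrastResult(comparison=label, estimate=diff, se=se,
                                  statistic=q, p_adj=min(1.0, p)))
    return out


def find_contrast(results: list[ContrastResult], a: str, b: str
                  ) -> ContrastResult:
    """The comparison between cells ``a`` and ``b`` (either orientation);
    the estimate is reported as a - b."""
    for r in results:
        left, right = r.comparison.split("-", 1) if r.comparison.count("-") == 1 \
            else (r.comparison[:len(r.comparison) // 2], "")
        if (left, right) == (a, b):
            return r
        if (left, right) == (b, a):
            return ContrastResult(comparison=f"{a}-{b}", estimate=-r.estimate,
                                  se=r.se, statistic=r.statistic, p_adj=r.p_adj)
    raise ContractError(f"no comparison between {a!r} and {b!r}")


# ---------------------------------------------------------------------------
# linear mixed model for multi-experiment panels
# ---------------------------------------------------------------------------

@dataclass
class LmeResult:
    """Estimated mean log10hz per fixed-factor level at each time."""

    effects: pd.DataFrame  # columns: level, time, estimate, se
    random_factors: list[str]
    dropped_factors: list[str]
    converged: bool
    model: object = field(default=None, repr=False)


def lme_effects(data: pd.DataFrame, fixed: str = "individual"
                ) -> LmeResult:
    """Mixed model: log10hz ~ fixed x time with nested random intercepts.

    ``fixed`` names the fixed factor (e.g. ``"diagnosis"`` or
    ``"individual"``); ``time`` is always crossed with it. Random
    intercepts are fit for whichever of individual, experiment and array
    remain below the fixed factor and vary in the data, encoded as nested
    components (composite grouping keys). Estimation is REML via
    ``statsmodels`` MixedLM. A singular or non-converging fit drops the
    finest variance component and retries, falling back to OLS when no
    random structure is estimable; dropped components are reported.
    """
    for col in (fixed, "time", "log10hz"):
        if col not in data.columns:
            raise InvalidInputError(f"missing column {col!r}")
    if data[fixed].nunique() < 2:
        raise InvalidInputError(f"fixed factor {fixed!r} needs >= 2 levels")

    data = data.copy()
    candidates = [c for c in ("individual", "experiment", "array")
                  if c != fixed and c in data.columns]
    # nest each factor inside the ones above it (composite keys)
    nested_keys: dict[str, pd.Series] = {}
    prefix: pd.Series | None = None
    usable: list[str] = []
    for c in candidates:
        key = (data[c].astype(str) if prefix is None
               else prefix + "/" + data[c].astype(str))
        nested_keys[c] = key
        prefix = key
        if key.nunique() > 1:
            usable.append(c)

    cell = data[fixed].astype(str) + _CELL_SEP + data["time"].astype(str)
    x = pd.get_dummies(cell, dtype=float)
    y = data["log10hz"].to_numpy(dtype=float)

    dropped: list[str] = []
    factors = list(usable)
    while True:
        if not factors:
            ols = sm.OLS(y, x.to_numpy()).fit()
            params, bse = ols.params, ols.bse
            converged = True
            model = ols
            break
        groups = nested_keys[factors[0]]
        vc = {c: pd.get_dummies(nested_keys[c], dtype=float)
              for c in factors[1:]}
        exog_vc = _vcspec(vc, groups) if vc else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = sm.MixedLM(y, x.to_numpy(), groups=groups.to_numpy(),
                                 exog_vc=exog_vc)
                res = mod.fit(reml=True, method=["lbfgs", "cg"], maxiter=200)
            singular = (res.cov_re.values.diagonal().min() < 1e-10
                        if res.cov_re.size else False)
            if not res.converged or (singular and len(factors) > 1):
                raise RuntimeError("singular or non-converged fit")
            params, bse = res.fe_params, res.bse_fe
            converged = bool(res.converged)
            model = res
            break
        except Exception:
            dropped.append(factors.pop())
            if dropped and not factors:
                warnings.warn("mixed model degenerate; falling back to OLS "
                              f"(dropped random factors: {dropped})",
                              stacklevel=2)

    rows = []
    for name, est, se in zip(x.columns, np.asarray(params), np.asarray(bse)):
        level, time = name.rsplit(_CELL_SEP, 1)
        rows.append({"level": level, "time": time,
                     "estimate": float(est), "se": float(se)})
    effects = pd.DataFrame(rows)
    return LmeResult(effects=effects, random_factors=factors,
                     dropped_factors=dropped, converged=converged, model=model)


def _vcspec(vc: dict[str, pd.DataFrame], groups: pd.Series):
    """Variance-component spec for MixedLM from nested-key dummy matrices."""
    from statsmodels.regression.mixed_linear_model import VCSpec
    group_labels = pd.unique(groups)
    names = list(vc.keys())
    colnames, mats = [], []
    for c in names:
        dummies = vc[c]
        percol, permat = [], []
        for g in group_labels:
            mask = (groups == g).to_numpy()
            sub = dummies.loc[mask]
            keep = sub.columns[(sub != 0).any(axis=0)]
            percol.append(list(keep))
            permat.append(sub[keep].to_numpy())
        colnames.append(percol)
        mats.append(permat)
    return VCSpec(names, colnames, mats)


# ---------------------------------------------------------------------------
# general linear hypothesis tests with single-step multivariate-t adjustment
# ---------------------------------------------------------------------------

_QMC_POWER = 17  # 2^17 ~ 1.3e5 quasi-random points


def _max_abs_t_cdf(t: float, corr: np.ndarray, df: int, seed: int = 20211) -> float:
    """P(max_j |T_j| <= t) for an equicoordinate multivariate t with the
    given correlation, by quasi-Monte-Carlo (Sobol, fixed seed)."""
    k = corr.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    evals = np.clip(evals, 0.0, None)
    root = evecs * np.sqrt(evals)
    sob = qmc.Sobol(d=k + 1, scramble=True, seed=seed)
    u = sob.random(2 ** _QMC_POWER)
    z = stats.norm.ppf(np.clip(u[:, :k], 1e-12, 1 - 1e-12)) @ root.T
    chi = stats.chi2.ppf(np.clip(u[:, k], 1e-12, 1 - 1e-12), df)
    scale = np.sqrt(chi / df)
    inside = (np.abs(z) <= t * scale[:, None]).all(axis=1)
    return float(inside.mean())


def glht_contrasts(params: np.ndarray, cov: np.ndarray, df: int,
                   contrasts: np.ndarray,
                   labels: list[str] | None = None) -> list[ContrastResult]:
    """Wald tests of ``contrasts @ params = 0`` with single-step
    multivariate-t familywise adjustment.

    ``contrasts`` is (k, p); its rows must match the coefficient vector.
    Perfectly correlated duplicate rows collapse to one effective contrast,
    and a single effective contrast reduces exactly to the two-sided t
    p-value.
    """
    params = np.asarray(params, dtype=float)
    contrasts = np.atleast_2d(np.asarray(contrasts, dtype=float))
    if contrasts.shape[1] != params.size:
        raise ContractError(
            f"contrast matrix has {contrasts.shape[1]} columns for "
            f"{params.size} coefficients")
    if labels is None:
        labels = [f"c{i + 1}" for i in range(contrasts.shape[0])]

    est = contrasts @ params
    vmat = contrasts @ np.asarray(cov, dtype=float) @ contrasts.T
    se = np.sqrt(np.diag(vmat))
    tstat = np.where(se > 0, est / se, 0.0)
    d = np.where(se > 0, se, 1.0)
    corr = vmat / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)

    # collapse duplicate (|rho| = 1) contrasts to the effective family
    keep: list[int] = []
    for i in range(corr.shape[0]):
        if not any(abs(corr[i, j]) > 1.0 - 1e-12 for j in keep):
            keep.append(i)
    eff_corr = corr[np.ix_(keep, keep)]

    out = []
    for i, lab in enumerate(labels):
        if eff_corr.shape[0] == 1:
            p = 2.0 * stats.t.sf(abs(tstat[i]), df)
        else:
            p = 1.0 - _max_abs_t_cdf(abs(float(tstat[i])), eff_corr, df)
        out.append(ContrastResult(comparison=lab, estimate=float(est[i]),
                                  se=float(se[i]), statistic=float(tstat[i]),
                                  p_adj=float(min(1.0, max(0.0, p)))))
    return out


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
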