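"""Cohort-level inference on per-cell endpoints.

Every data point is one cell. General linear models (Gaussian errors) are
fit by ordinary least squares with treatment indicators and experiment day
as a fixed blocking factor; an interaction is included when two
experimental factors are present. Because cells from the same larva are
correlated, all inference uses cluster-robust (CR1 sandwich) standard
errors clustered by larva, with a t reference distribution on
(number of larvae - 1) degrees of freedom. Endpoints may be natural-log
transformed, in which case estimated means and contrasts are reported
back-transformed (means and fold-change ratios). No multiplicity
adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import dmatrix
from scipy import stats as sps

__all__ = [
    "GlmSpec",
    "StatsResult",
    "DiagnosticsReport",
    "fit_glm",
    "cluster_robust_cov",
    "diagnostics",
]


@dataclass(frozen=True)
class GlmSpec:
    """Specification of one endpoint model.

    treatment : one factor name or a list of factor names (an interaction
        is included when >= 2 factors and ``interaction`` is True).
    block : day blocking factor (None to omit).
    cluster : larva cluster variable (None for classical OLS inference).
    """

    outcome: str
    treatment: str | tuple[str, ...] = "treatment"
    interaction: bool = True
    block: str | None = "day_id"
    log_transform: bool = False
    cluster: str | None = "larva_id"

    @property
    def factors(self) -> tuple[str, ...]:
        if isinstance(self.treatment, str):
            return (self.treatment,)
        return tuple(self.treatment)


@dataclass
class StatsResult:
    """Coefficients, robust covariance, estimated means, and contrasts."""

    spec: GlmSpec
    params: pd.Series
    cov: pd.DataFrame
    group_means: pd.DataFrame  # columns: group, mean, ci_low, ci_high
    contrasts: pd.DataFrame  # columns: group_a, group_b, type, estimate, ci_low, ci_high, p_value
    n_cells: int
    n_larvae: int
    n_days: int
    df_inference: float
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)


def cluster_robust_cov(fit, cluster_ids) -> np.ndarray:
    """CR1 cluster-robust sandwich covariance for an OLS fit.

    ``fit`` is a statsmodels regression results object (or anything with
    ``model.exog`` and ``resid``). The meat sums per-cluster score outer
    products; the small-sample scaling is G/(G-1) * (n-1)/(n-k). With every
    observation its own cluster this reduces to the HC1 estimator.
    """
    X = np.asarray(fit.model.exog, dtype=float)
    u = np.asarray(fit.resid, dtype=float)
    groups = np.asarray(cluster_ids)
    if groups.shape[0] != X.shape[0]:
        raise ValueError("cluster_ids length does not match the design")
    labels = np.unique(groups)
    n_groups = labels.size
    if n_groups < 2:
        raise ValueError("cluster-robust covariance requires >= 2 clusters")
    n, k = X.shape
    bread = np.linalg.pinv(X.T @ X)
    meat = np.zeros((k, k))
    for g in labels:
        sel = groups == g
        s = X[sel].T @ u[sel]
        meat += np.outer(s, s)
    c = (n_groups / (n_groups - 1.0)) * ((n - 1.0) / (n - k))
    return c * bread @ meat @ bread


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank growth
        aliased = []
        r = 0
        for j in range(X.shape[1]):
            new_rank = np.linalg.matrix_rank(X[:, : j + 1])
            if new_rank == r:
                aliased.append(names[j])
            r = new_rank
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def fit_glm(cohort_table: pd.DataFrame, spec: GlmSpec) -> StatsResult:
    """Fit the endpoint GLM and report estimated means and contrasts.

    Estimated group means are computed at balanced day weights (each day
    weighted equally). Contrasts are pairwise differences between treatment
    groups on the model scale; under a log transform they are reported as
    fold-change ratios with back-transformed CIs.
    """
    cols = [spec.outcome, *spec.factors]
    if spec.block:
        cols.append(spec.block)
    if spec.cluster:
        cols.append(spec.cluster)
    missing = [c for c in cols if c not in cohort_table.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    data = cohort_table[cols].dropna().copy()
    if len(data) == 0:
        raise ValueError("no complete rows to fit")

    yname = spec.outcome
    if spec.log_transform:
        if (data[yname] <= 0).any():
            raise ValueError(
                f"log transform requested but {yname} has nonpositive values"
            )
        data["_y"] = np.log(data[yname].astype(float))
    else:
        data["_y"] = data[yname].astype(float)

    join = " * " if (spec.interaction and len(spec.factors) > 1) else " + "
    rhs = join.join(f"C({f})" for f in spec.factors)
    if spec.block:
        rhs += f" + C({spec.block})"
    formula = f"_y ~ {rhs}"

    model = smf.ols(formula, data=data)
    _check_full_rank(model.exog, list(model.exog_names))

    groups = None
    if spec.cluster:
        groups = data[spec.cluster].to_numpy()
        n_larvae = int(pd.unique(groups).size)
        if n_larvae < 2:
            raise ValueError("cluster-robust inference requires >= 2 larvae")
        res = model.fit(cov_type="cluster", cov_kwds={"groups": pd.Categorical(groups).codes}, use_t=True)
        df_inf = float(n_larvae - 1)
        V = np.asarray(res.cov_params())
    else:
        res = model.fit(use_t=True)
        n_larvae = len(data)
        df_inf = float(res.df_resid)
        V = np.asarray(res.cov_params())

    design_info = model.data.design_info
    days = sorted(data[spec.block].unique()) if spec.block else [None]
    levels_per_factor = [sorted(data[f].unique()) for f in spec.factors]
    beta = np.asarray(res.params)
    tcrit = sps.t.ppf(0.975, df_inf)

    def _L_for(combo) -> np.ndarray:
        rows = []
        for d in days:
            rec = {f: [lvl] for f, lvl in zip(spec.factors, combo)}
            if spec.block:
                rec[spec.block] = [d]
            rows.append(np.asarray(dmatrix(design_info, pd.DataFrame(rec)))[0])
        return np.mean(rows, axis=0)

    mean_rows = []
    combos = list(product(*levels_per_factor))
    Ls = {}
    for combo in combos:
        L = _L_for(combo)
        Ls[combo] = L
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        lo, hi = est - tcrit * se, est + tcrit * se
        if spec.log_transform:
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        mean_rows.append(
            {"group": ":".join(map(str, combo)), "mean": est, "ci_low": lo, "ci_high": hi}
        )

    contrast_rows = []
    for a, b in combinations(combos, 2):
        L = Ls[a] - Ls[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        tval = est / se if se > 0 else np.inf
        p = float(2.0 * sps.t.sf(abs(tval), df_inf))
        lo, hi = est - tcrit * se, est + tcrit * se
        if spec.log_transform:
            row = {"type": "ratio", "estimate": np.exp(est), "ci_low": np.exp(lo), "ci_high": np.exp(hi)}
        else:
            row = {"type": "difference", "estimate": est, "ci_low": lo, "ci_high": hi}
        contrast_rows.append(
            {
                "group_a": ":".join(map(str, a)),
                "group_b": ":".join(map(str, b)),
                **row,
                "p_value": max(p, np.finfo(float).tiny),
            }
        )

    return StatsResult(
        spec=spec,
        params=pd.Series(beta, index=res.model.exog_names),
        cov=pd.DataFrame(V, index=res.model.exog_names, columns=res.model.exog_names),
        group_means=pd.DataFrame(mean_rows),
        contrasts=pd.DataFrame(contrast_rows),
        n_cells=len(data),
        n_larvae=n_larvae if spec.cluster else 0,
        n_days=len(days) if spec.block else 0,
        df_inference=df_inf,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


@dataclass
class DiagnosticsReport:
    """Plot-ready residual summaries for model checking."""

    resid_vs_fitted: pd.DataFrame
    normal_quantiles: pd.DataFrame
    quartile_resid_sd: np.ndarray
    heteroskedastic: bool


def diagnostics(result: StatsResult) -> DiagnosticsReport:
    """Residual-vs-fitted and normal-quantile tables, plus a gross
    heteroskedasticity flag (residual SD doubling across fitted-value
    quartiles)."""
    fitted = np.asarray(result.fitted, dtype=float)
    resid = np.asarray(result.residuals, dtype=float)
    order = np.argsort(resid)
    n = resid.size
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame(
        {"theoretical_quantile": theo, "sample_quantile": resid[order]}
    )
    rvf = pd.DataFrame({"fitted": fitted, "residual": resid})
    # residual SD by fitted-value quartile
    qs = np.quantile(fitted, [0.25, 0.5, 0.75])
    bins = np.digitize(fitted, qs)
    sds = np.array(
        [resid[bins == b].std(ddof=1) if np.sum(bins == b) > 1 else np.nan for b in range(4)]
    )
    finite = sds[np.isfinite(sds)]
    flag = bool(finite.size >= 2 and finite.max() >= 2.0 * finite.min())
    return DiagnosticsReport(
        resid_vs_fitted=rvf,
        normal_quantiles=qq,
        quartile_resid_sd=sds,
        heteroskedastic=flag,
    )
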