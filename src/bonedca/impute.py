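"""Multiple imputation by chained equations, Rubin's-rules pooling, and
the Kaplan-Meier congeniality diagnostic.

The chained-equations engine treats the cohort's incomplete variables with
type-appropriate conditional models:

* continuous (log PSA, percent positive cores): Bayesian linear regression
  with predictive-mean matching (type-1 PMM, k = 5 donors), so imputed
  values are always observed donor values;
* ordered categorical (ISUP grade group, T-stage index): PMM on the ordinal
  code — donors keep imputations on the valid ordinal lattice;
* binary (nodal stage, bone-scan positivity): Bayesian logistic regression
  (a parameter draw from the asymptotic posterior, then a Bernoulli draw).

Predictors of every conditional model include age, treatment setting,
diagnosis year and survival encoded as (log time, event indicator), so the
missing-at-random mechanisms the generator emulates (selective scanning of
higher-risk patients; private-setting data restriction) are conditioned on.
Variables are visited in increasing order of missingness, ties broken
alphabetically.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .cohort import T_STAGES, grade_group, t_stage_index

__all__ = [
    "ImputationError",
    "ImputedCohortSet",
    "PooledEstimate",
    "mice_impute",
    "rubin_pool",
    "km_diagnostic",
]

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


#: representative Gleason pattern for each grade group (decoding imputations)
_GG_TO_PATTERN = {1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}

#: working-matrix variables that may be imputed, with their conditional type
_IMPUTABLE = {
    "log_psa": "continuous",
    "pct_pos_cores": "continuous",
    "grade_group": "ordinal",
    "t_index": "ordinal",
    "n_stage_positive": "binary",
    "scan_positive": "binary",
}

#: always-complete predictors entering every conditional model
_COMPLETE = ["age_years", "log_survival", "dead", "private", "year_of_diagnosis"]


@dataclass
class ImputedCohortSet:
    """m completed cohort tables plus the provenance needed to pool and
    to separate observed from imputed cells."""

    m: int
    iterations: int
    seed: int
    datasets: list[pd.DataFrame]
    source: pd.DataFrame
    spec: dict = field(default_factory=dict)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of one statistic across imputed datasets."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci95: tuple[float, float]
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


# ---------------------------------------------------------------------------
# encoding

def _encode(cohort: pd.DataFrame) -> pd.DataFrame:
    work = pd.DataFrame(index=cohort.index)
    work["age_years"] = cohort["age_years"].astype(float)
    work["log_survival"] = np.log1p(cohort["survival_months"].astype(float))
    work["dead"] = cohort["dead"].astype(float)
    work["private"] = (cohort["treatment_setting"] == "private").astype(float)
    work["year_of_diagnosis"] = cohort["year_of_diagnosis"].astype(float)
    work["log_psa"] = np.log(cohort["psa_ng_ml"].astype(float))
    work["pct_pos_cores"] = cohort["pct_pos_cores"].astype(float)
    work["grade_group"] = grade_group(
        cohort["gleason_primary"], cohort["gleason_secondary"]
    )
    work["t_index"] = t_stage_index(cohort["t_stage"])
    work["n_stage_positive"] = cohort["n_stage_positive"].astype(float)
    scan = cohort["scan_result"]
    work["scan_positive"] = np.where(
        scan == "positive", 1.0, np.where(scan == "negative", 0.0, np.nan)
    )
    return work


def _decode(work: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
    out = template.copy()
    miss_psa = out["psa_ng_ml"].isna()
    out.loc[miss_psa, "psa_ng_ml"] = np.exp(work.loc[miss_psa, "log_psa"]).round(4)
    miss_cores = out["pct_pos_cores"].isna()
    out.loc[miss_cores, "pct_pos_cores"] = work.loc[miss_cores, "pct_pos_cores"]
    miss_gl = out["gleason_primary"].isna() | out["gleason_secondary"].isna()
    gg = work.loc[miss_gl, "grade_group"].round().clip(1, 5).astype(int)
    out.loc[miss_gl, "gleason_primary"] = [_GG_TO_PATTERN[g][0] for g in gg]
    out.loc[miss_gl, "gleason_secondary"] = [_GG_TO_PATTERN[g][1] for g in gg]
    miss_t = out["t_stage"].isna()
    t_codes = work.loc[miss_t, "t_index"].round().clip(0, 9).astype(int)
    out.loc[miss_t, "t_stage"] = [T_STAGES[i] for i in t_codes]
    miss_n = out["n_stage_positive"].isna()
    out.loc[miss_n, "n_stage_positive"] = work.loc[miss_n, "n_stage_positive"]
    unscanned = ~out["scan_result"].isin(["positive", "negative"])
    out.loc[unscanned, "scan_result"] = np.where(
        work.loc[unscanned, "scan_positive"] > 0.5, "positive", "negative"
    )
    return out


# ---------------------------------------------------------------------------
# conditional draws

def _pmm_draw(rng, X_obs, y_obs, X_mis, k: int = 5) -> np.ndarray:
    """Type-1 predictive-mean matching with a Bayesian linear draw."""
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + 1e-8 * np.eye(p)
    beta = np.linalg.solve(XtX, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_star = sigma2 * dof / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(XtX)
    cov = (cov + cov.T) / 2 + 1e-12 * np.eye(p)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")

    yhat_obs = X_obs @ beta
    yhat_mis = X_mis @ beta_star

    order = np.argsort(yhat_obs, kind="stable")
    sorted_hat = yhat_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_hat, yhat_mis)
    # candidate window of 2k neighbours around the insertion point
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n - 1)
    dist = np.abs(sorted_hat[cand] - yhat_mis[:, None])
    kk = min(k, cand.shape[1])
    nearest = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    pick = nearest[np.arange(len(yhat_mis)), rng.integers(0, kk, len(yhat_mis))]
    donors = cand[np.arange(len(yhat_mis)), pick]
    return sorted_y[donors]


def _logistic_draw(rng, X_obs, y_obs, X_mis) -> np.ndarray:
    """Bernoulli imputation from a Bayesian logistic conditional model;
    falls back to a marginal draw when the fit degenerates."""
    classes = np.unique(y_obs)
    if len(classes) < 2:
        return np.full(len(X_mis), classes[0], dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit(maxiter=50)
            beta = np.asarray(res.params, dtype=float)
            cov = np.asarray(res.cov_params(), dtype=float)
        cov = (cov + cov.T) / 2 + 1e-10 * np.eye(len(beta))
        beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
        p = expit(X_mis @ beta_star)
        if not np.all(np.isfinite(p)):
            raise FloatingPointError("non-finite probabilities")
    except Exception as exc:  # separation / singular fit
        warnings.warn(
            f"logistic conditional model failed ({exc}); falling back to a "
            "marginal draw",
            stacklevel=2,
        )
        logger.warning("logistic conditional fit failed: %s", exc)
        p = np.full(len(X_mis), float(np.mean(y_obs)))
    return (rng.random(len(X_mis)) < p).astype(float)


# ---------------------------------------------------------------------------
# the chained-equations sweep

def mice_impute(
    cohort: pd.DataFrame,
    spec: dict | None = None,
    m: int = 100,
    iterations: int = 100,
    seed: int = 0,
    pmm_donors: int = 5,
) -> ImputedCohortSet:
    """Multiply impute a cohort's missing predictors and scan outcomes.

    Returns ``m`` completed datasets; observed cells are bit-identical
    across datasets and to the input.  ``spec`` may override the conditional
    type per working variable ({"log_psa": "continuous", ...}).
    """
    if m < 1 or iterations < 1:
        raise ImputationError("m and iterations must be >= 1")
    if len(cohort) == 0:
        raise ImputationError("empty cohort")
    types = dict(_IMPUTABLE)
    if spec:
        types.update(spec)

    work0 = _encode(cohort)
    miss = {v: work0[v].isna().to_numpy() for v in types}
    for v, mk in miss.items():
        if mk.all():
            raise ImputationError(f"variable {v!r} is 100% missing")
    targets = [v for v in types if miss[v].any()]
    # visit sequence: increasing missingness, ties alphabetical
    targets.sort(key=lambda v: (miss[v].mean(), v))

    children = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for d in range(m):
        rng = np.random.default_rng(children[d])
        work = work0.copy()
        for v in targets:
            obs_vals = work0.loc[~miss[v], v].to_numpy()
            work.loc[miss[v], v] = rng.choice(obs_vals, size=int(miss[v].sum()))
        for _ in range(iterations if targets else 0):
            for v in targets:
                preds = _COMPLETE + [u for u in types if u != v]
                X = np.column_stack(
                    [np.ones(len(work))] + [work[u].to_numpy(dtype=float) for u in preds]
                )
                y = work0[v].to_numpy(dtype=float)
                mk = miss[v]
                if types[v] == "binary":
                    drawn = _logistic_draw(rng, X[~mk], y[~mk], X[mk])
                else:
                    drawn = _pmm_draw(rng, X[~mk], y[~mk], X[mk], k=pmm_donors)
                col = work[v].to_numpy(dtype=float)
                col[mk] = drawn
                work[v] = col
        datasets.append(_decode(work, cohort))

    return ImputedCohortSet(
        m=m,
        iterations=iterations,
        seed=seed,
        datasets=datasets,
        source=cohort.copy(),
        spec=types,
    )


# ---------------------------------------------------------------------------
# Rubin's rules

def rubin_pool(
    estimates, variances, df_com: float | None = None, level: float = 0.95
) -> PooledEstimate:
    """Combine per-dataset estimates and variances across imputations.

    Pooled estimate is the mean; total variance is within + (1 + 1/m) x
    between; degrees of freedom follow Rubin's large-sample formula, with
    the Barnard-Rubin small-sample adjustment when a complete-data ``df_com``
    is supplied.
    """
    q = np.asarray(list(estimates), dtype=float)
    u = np.asarray(list(variances), dtype=float)
    if q.size == 0:
        raise ImputationError("empty estimate list")
    if q.shape != u.shape:
        raise ImputationError("estimates and variances differ in length")
    if np.any(u < 0):
        raise ImputationError("negative variance")
    m = q.size
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = ubar + (1 + 1 / m) * b

    if m == 1 or b == 0.0:
        df = np.inf
    else:
        r = (1 + 1 / m) * b / ubar if ubar > 0 else np.inf
        df = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else m - 1.0
        if df_com is not None and np.isfinite(df_com):
            lam = (1 + 1 / m) * b / t
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)

    alpha = 1 - level
    crit = stats.norm.ppf(1 - alpha / 2) if np.isinf(df) else stats.t.ppf(
        1 - alpha / 2, df
    )
    half = crit * np.sqrt(t)
    return PooledEstimate(
        estimate=qbar,
        within_var=ubar,
        between_var=b,
        total_var=t,
        df=float(df),
        ci95=(qbar - half, qbar + half),
        m=m,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier congeniality diagnostic

def km_diagnostic(
    imputed_set: ImputedCohortSet, time_grid=None
) -> pd.DataFrame:
    """Survival curves contrasting observed vs imputed scan results.

    Returns a tidy table (stratum, time, survival, n, n_events) with strata
    observed-positive / imputed-positive / observed-negative /
    imputed-negative; imputed strata are averaged across the m datasets.
    A stratum without events is flagged (``n_events = 0``) and its curve is
    constant at 1.
    """
    from lifelines import KaplanMeierFitter

    src = imputed_set.source
    if src["survival_months"].isna().any():
        raise ImputationError("survival fields must be complete")
    if time_grid is None:
        tmax = float(src["survival_months"].max())
        time_grid = np.linspace(0.0, tmax, 61)
    time_grid = np.asarray(time_grid, dtype=float)

    obs_pos = (src["scan_result"] == "positive").to_numpy()
    obs_neg = (src["scan_result"] == "negative").to_numpy()
    missing = ~(obs_pos | obs_neg)

    def _km(mask: np.ndarray, df: pd.DataFrame):
        t = df.loc[mask, "survival_months"].to_numpy(dtype=float)
        e = df.loc[mask, "dead"].to_numpy(dtype=bool)
        if mask.sum() == 0:
            return np.full(len(time_grid), np.nan), 0, 0
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        surv = (
            kmf.survival_function_at_times(time_grid).to_numpy(dtype=float)
        )
        return surv, int(mask.sum()), int(e.sum())

    rows = []
    for name, mask in (("observed-positive", obs_pos), ("observed-negative", obs_neg)):
        surv, n, ev = _km(mask, src)
        rows.append((name, surv, n, ev))

    for name, want_pos in (("imputed-positive", True), ("imputed-negative", False)):
        curves, ns, evs = [], [], []
        for ds in imputed_set.datasets:
            imputed_state = (ds["scan_result"] == "positive").to_numpy()
            mask = missing & (imputed_state == want_pos)
            surv, n, ev = _km(mask, ds)
            curves.append(surv)
            ns.append(n)
            evs.append(ev)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            surv = np.nanmean(np.vstack(curves), axis=0)
        rows.append((name, surv, int(np.mean(ns)), int(np.mean(evs))))

    out = []
    for name, surv, n, ev in rows:
        for t, s in zip(time_grid, surv):
            out.append(
                {"stratum": name, "time": t, "survival": s, "n": n, "n_events": ev}
            )
    return pd.DataFrame(out)
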