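"""External-validation metrics: calibration slope, calibration-in-the-large
and rank-based discrimination (AUC), pooled across imputed datasets.

Conventions
-----------
* Calibration slope: coefficient of logit(predicted risk) in a logistic
  regression of the observed binary outcome; 1 is ideal.
* Calibration-in-the-large: intercept of the same regression with the slope
  fixed at one (the logit of predicted risk enters as an offset); 0 is
  ideal; a *positive* value means risks were under-estimated on average.
* AUC: Mann-Whitney concordance with ties counted half; variance by the
  DeLong placement estimator.
* Models with fewer than four distinct predicted-risk levels are excluded
  from calibration (a two- or three-group model cannot support a
  meaningful slope), and models without numeric predicted risks are
  excluded entirely from calibration; discrimination for categorical and
  guideline models uses the group-ordinal rank as the score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import rankdata

from .impute import ImputedCohortSet, PooledEstimate, rubin_pool
from .models import ModelRegistry, NoNumericRiskError, RiskModel

__all__ = [
    "CalibrationError",
    "calibration_slope",
    "calibration_in_the_large",
    "auc",
    "categorical_predicted_risk",
    "pooled_validation",
]

EPS = 1e-6  # logit clipping for boundary risks


class CalibrationError(ValueError):
    """Degenerate inputs: constant predictions or single-class outcomes."""


def _check(predicted, observed):
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-d arrays")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("observed outcomes must be binary 0/1")
    if y.min() == y.max():
        raise CalibrationError("single-class outcomes")
    return p, y


def calibration_slope(predicted, observed, eps: float = EPS) -> tuple[float, float]:
    """Slope of observed outcome on logit(predicted risk).

    Returns (estimate, variance).  Predictions are clipped into
    (eps, 1 - eps) before the logit.
    """
    p, y = _check(predicted, observed)
    x = logit(np.clip(p, eps, 1 - eps))
    if np.unique(x).size < 2:
        raise CalibrationError("constant predictions: slope undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    return float(res.params[1]), float(res.cov_params()[1, 1])


def calibration_in_the_large(
    predicted, observed, eps: float = EPS
) -> tuple[float, float]:
    """Calibration intercept with the slope fixed at one.

    Returns (estimate, variance).  Positive values indicate the model
    under-estimates risk on average; negative values over-estimation.
    """
    p, y = _check(predicted, observed)
    x = logit(np.clip(p, eps, 1 - eps))
    if np.unique(x).size < 2:
        raise CalibrationError("constant predictions: calibration undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(
            y, np.ones((len(y), 1)), offset=x, family=sm.families.Binomial()
        ).fit()
    return float(res.params[0]), float(res.cov_params()[0, 0])


def auc(scores, observed) -> tuple[float, float]:
    """Rank (Mann-Whitney) AUC with ties counted half, plus its DeLong
    placement variance.  Returns (estimate, variance)."""
    s, y = _check(scores, observed)
    pos = s[y == 1]
    neg = s[y == 0]
    n1, n0 = len(pos), len(neg)
    ranks = rankdata(s)
    a = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    # DeLong placements via sorted searchsorted counts
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    below = np.searchsorted(neg_sorted, pos, side="left")
    ties_n = np.searchsorted(neg_sorted, pos, side="right") - below
    v10 = (below + 0.5 * ties_n) / n0
    above = n1 - np.searchsorted(pos_sorted, neg, side="right")
    ties_p = np.searchsorted(pos_sorted, neg, side="right") - np.searchsorted(
        pos_sorted, neg, side="left"
    )
    v01 = (above + 0.5 * ties_p) / n1
    s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
    var = s10 / n1 + s01 / n0
    return float(a), var


def categorical_predicted_risk(model: RiskModel, risk_group) -> float:
    """The development-study positivity rate configured for a risk group.

    Raises :class:`bonedca.models.NoNumericRiskError` when no rate is
    configured — the model is then excluded from calibration."""
    return model.group_predicted_risk(risk_group)


@dataclass
class _MetricAcc:
    estimates: list
    variances: list
    failures: int = 0


def pooled_validation(
    imputed_set: ImputedCohortSet,
    registry: ModelRegistry,
    min_levels: int = 4,
    df_com: float | None = None,
) -> pd.DataFrame:
    """Per-model calibration and discrimination, pooled with Rubin's rules.

    Returns a tidy table (model, metric, estimate, se, ci_low, ci_high,
    n_failed) — the machine-readable twin of a published validation table.
    A model whose metric fails in some datasets is reported with the
    failure count, never silently averaged; when every dataset fails the
    estimate is NaN.
    """
    rows = []
    for model in registry:
        accs: dict[str, _MetricAcc] = {
            "auc": _MetricAcc([], []),
            "calibration_slope": _MetricAcc([], []),
            "calibration_in_the_large": _MetricAcc([], []),
        }
        for ds in imputed_set.datasets:
            y = (ds["scan_result"] == "positive").to_numpy(dtype=float)
            try:
                est, var = auc(model.scores(ds), y)
                accs["auc"].estimates.append(est)
                accs["auc"].variances.append(var)
            except (CalibrationError, ValueError):
                accs["auc"].failures += 1

            try:
                risks = model.risks(ds)
            except NoNumericRiskError:
                accs["calibration_slope"].failures += 1
                accs["calibration_in_the_large"].failures += 1
                continue
            if np.unique(risks).size < min_levels:
                # three or fewer risk levels: calibration not meaningful
                accs["calibration_slope"].failures += 1
                accs["calibration_in_the_large"].failures += 1
                continue
            for metric, fn in (
                ("calibration_slope", calibration_slope),
                ("calibration_in_the_large", calibration_in_the_large),
            ):
                try:
                    est, var = fn(risks, y)
                    accs[metric].estimates.append(est)
                    accs[metric].variances.append(var)
                except CalibrationError:
                    accs[metric].failures += 1

        for metric, acc in accs.items():
            if acc.estimates:
                pooled = rubin_pool(acc.estimates, acc.variances, df_com=df_com)
                rows.append(
                    {
                        "model": model.name,
                        "metric": metric,
                        "estimate": pooled.estimate,
                        "se": pooled.se,
                        "ci_low": pooled.ci95[0],
                        "ci_high": pooled.ci95[1],
                        "n_failed": acc.failures,
                    }
                )
            else:
                rows.append(
                    {
                        "model": model.name,
                        "metric": metric,
                        "estimate": np.nan,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "n_failed": acc.failures,
                    }
                )
    return pd.DataFrame(rows)
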