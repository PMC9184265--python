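"""Published bone-scan staging models and their recommended strategies.

Eleven models are registered: three continuous (Chybowski, Ho, Wang), five
categorical (Briganti, Gnanapragasam/Cambridge, ISUP grade grouping, Lai,
O'Sullivan) and three guideline stratifications (AUA 2018, EAU 2020,
NCCN 2019).  Each model exposes

* a discrimination *score* (higher = higher risk of a positive scan),
* zero or more fixed staging *strategies* (binary scan/no-scan predicates),
* optionally a numeric *risk* in (0, 1) — native for continuous models,
  via configured per-group development positivity rates for categorical ones.

All rules follow their published wording with strict ">" and inclusive
"≥" thresholds.  Models evaluate on complete (post-imputation) records
only; a missing required predictor raises :class:`MissingPredictorError`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import grade_group, t_stage_index

__all__ = [
    "MissingPredictorError",
    "FormUnavailableError",
    "NoNumericRiskError",
    "RiskPrediction",
    "RiskModel",
    "ModelRegistry",
    "default_registry",
    "load_registry_config",
    "wang_score",
    "wang_probability",
    "classify_wang",
    "classify_eau",
    "classify_eau_high_risk",
    "classify_aua",
    "classify_nccn",
    "classify_gnanapragasam",
    "gnanapragasam_group",
    "classify_isup",
    "isup_grade_group",
    "classify_simple_psa",
    "classify_ho",
    "classify_osullivan",
    "classify_briganti",
    "briganti_group",
    "lai_psa_group",
    "eau_risk_stratum",
    "aua_risk_stratum",
    "nccn_risk_stratum",
]


class MissingPredictorError(ValueError):
    """A required predictor is missing; models run post-imputation only."""


class FormUnavailableError(LookupError):
    """A continuous probability form was requested for a model that has no
    registered coefficients/lookup table."""


class NoNumericRiskError(LookupError):
    """The model reports no numeric predicted risk (guideline models, or
    categorical models without configured development rates)."""


# ---------------------------------------------------------------------------
# record plumbing

def _as_frame(records) -> tuple[pd.DataFrame, bool]:
    if isinstance(records, pd.DataFrame):
        return records, False
    if isinstance(records, pd.Series):
        return records.to_frame().T, True
    if isinstance(records, Mapping):
        return pd.DataFrame([records]), True
    raise TypeError(f"cannot interpret records of type {type(records)!r}")


def _require(df: pd.DataFrame, cols: list[str], model: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise MissingPredictorError(f"{model}: column {c!r} absent")
        if pd.isna(df[c]).any():
            raise MissingPredictorError(
                f"{model}: missing values in {c!r}; complete records required"
            )


def _fields(df: pd.DataFrame):
    psa = df["psa_ng_ml"].to_numpy(dtype=float)
    gg = grade_group(df["gleason_primary"], df["gleason_secondary"])
    gsum = df["gleason_primary"].to_numpy(dtype=float) + df[
        "gleason_secondary"
    ].to_numpy(dtype=float)
    t_idx = t_stage_index(df["t_stage"])
    return psa, gg, gsum, t_idx


def _ret(values, scalar: bool):
    arr = np.asarray(values)
    if scalar:
        v = arr.reshape(-1)[0]
        return v.item() if hasattr(v, "item") else v
    return arr


# ---------------------------------------------------------------------------
# Wang (continuous, with the printed decision score D)

def wang_score(psa, t_stage, gleason_primary, gleason_secondary):
    """Wang decision score.

    D = -6.40 + 2.39*[T4] + 0.87*ln(PSA + 1) + 0.93*[GS >= 4+3] + 2.169,
    where [T4] is 1 for clinical stage T4 and [GS >= 4+3] is 1 when the
    Gleason pattern is 4+3 or worse.  Works on scalars or arrays.
    """
    psa = np.asarray(psa, dtype=float)
    if np.any(psa <= 0):
        raise MissingPredictorError("wang: PSA must be positive")
    t4 = (np.asarray(t_stage_index(t_stage)) == 9).astype(float)
    gg = grade_group(gleason_primary, gleason_secondary)
    gs_high = (np.asarray(gg) >= 3).astype(float)
    d = -6.40 + 2.39 * t4 + 0.87 * np.log(psa + 1.0) + 0.93 * gs_high + 2.169
    if d.ndim == 0:
        return float(d)
    return d


def wang_probability(psa, t_stage, gleason_primary, gleason_secondary):
    """Positivity probability as the inverse logit of the Wang score."""
    return expit(wang_score(psa, t_stage, gleason_primary, gleason_secondary))


def classify_wang(records, invert: bool = False):
    """Wang staging rule, exactly as printed: scan when D < 0.

    The printed direction conflicts with the score's risk-increasing
    coefficients; ``invert=True`` flips it to scan when D > 0 without
    guessing the source's intent.
    """
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "wang")
    d = wang_score(
        df["psa_ng_ml"], df["t_stage"], df["gleason_primary"], df["gleason_secondary"]
    )
    d = np.atleast_1d(d)
    scan = d > 0 if invert else d < 0
    return _ret(scan, scalar)


# ---------------------------------------------------------------------------
# guideline stratifications

def classify_eau(records):
    """EAU 2020 recommendation: scan intermediate-risk disease with Gleason
    4+3 or any high-risk disease, i.e. PSA > 20, T >= T2c or GS >= 4+3."""
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "eau")
    psa, gg, _, t_idx = _fields(df)
    scan = (psa > 20) | (t_idx >= 5) | (gg >= 3)
    return _ret(scan, scalar)


def classify_eau_high_risk(records):
    """Scan EAU high-risk patients only: PSA > 20, GS >= 8 or T >= T3.

    Narrower than :func:`classify_eau`, which additionally scans Gleason 4+3
    intermediate-risk disease."""
    df, scalar = _as_frame(records)
    _require(
        df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "eau-high"
    )
    psa, _, gsum, t_idx = _fields(df)
    scan = (psa > 20) | (gsum >= 8) | (t_idx >= 6)
    return _ret(scan, scalar)


def classify_aua(records):
    """AUA 2018: scan unfavourable-intermediate risk and higher, i.e.
    PSA > 20, PSA > 10 with GS 3+4, GS >= 4+3, or T >= T2b."""
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "aua")
    psa, gg, _, t_idx = _fields(df)
    scan = (psa > 20) | ((psa > 10) & (gg == 2)) | (gg >= 3) | (t_idx >= 4)
    return _ret(scan, scalar)


def classify_nccn(records):
    """NCCN 2019: scan unfavourable-intermediate risk or higher, i.e.
    T >= T3, PSA > 20, GS >= 8, or any of {T2b-T2c, GS 7, PSA 10-20}
    combined with >= 50% positive biopsy cores."""
    df, scalar = _as_frame(records)
    _require(
        df,
        [
            "psa_ng_ml",
            "t_stage",
            "gleason_primary",
            "gleason_secondary",
            "pct_pos_cores",
        ],
        "nccn",
    )
    psa, _, gsum, t_idx = _fields(df)
    cores = df["pct_pos_cores"].to_numpy(dtype=float)
    intermediate_feature = (
        ((t_idx == 4) | (t_idx == 5)) | (gsum == 7) | ((psa >= 10) & (psa <= 20))
    )
    scan = (
        (t_idx >= 6)
        | (psa > 20)
        | (gsum >= 8)
        | (intermediate_feature & (cores >= 50))
    )
    return _ret(scan, scalar)


def eau_risk_stratum(records):
    """EAU three-level risk stratum as an ordinal 0/1/2 (low/int/high);
    used as the discrimination score for the EAU guideline model."""
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "eau")
    psa, gg, gsum, t_idx = _fields(df)
    high = (psa > 20) | (gsum >= 8) | (t_idx >= 5)
    low = ~high & (psa < 10) & (gg == 1) & (t_idx <= 3)
    return _ret(np.where(high, 2, np.where(low, 0, 1)), scalar)


def aua_risk_stratum(records):
    """AUA stratum ordinal 0-3: low / favourable-int / unfavourable-int /
    high (high: PSA > 20, GS >= 8 or T >= T3)."""
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "aua")
    psa, gg, gsum, t_idx = _fields(df)
    high = (psa > 20) | (gsum >= 8) | (t_idx >= 6)
    unfav = ~high & (((psa > 10) & (gg == 2)) | (gg >= 3) | (t_idx >= 4))
    fav = ~high & ~unfav & (((psa >= 10) & (psa <= 20)) | (gg == 2) | (t_idx >= 4))
    return _ret(np.select([high, unfav, fav], [3, 2, 1], default=0), scalar)


def nccn_risk_stratum(records):
    """NCCN stratum ordinal 0-3: low / favourable-int / unfavourable-int /
    high-or-very-high."""
    df, scalar = _as_frame(records)
    _require(
        df,
        [
            "psa_ng_ml",
            "t_stage",
            "gleason_primary",
            "gleason_secondary",
            "pct_pos_cores",
        ],
        "nccn",
    )
    psa, _, gsum, t_idx = _fields(df)
    cores = df["pct_pos_cores"].to_numpy(dtype=float)
    high = (t_idx >= 6) | (psa > 20) | (gsum >= 8)
    feature = ((t_idx == 4) | (t_idx == 5)) | (gsum == 7) | ((psa >= 10) & (psa <= 20))
    unfav = ~high & feature & (cores >= 50)
    fav = ~high & ~unfav & feature
    return _ret(np.select([high, unfav, fav], [3, 2, 1], default=0), scalar)


# ---------------------------------------------------------------------------
# categorical models

def gnanapragasam_group(records, group5_rule: Callable | None = None):
    """Five-tier Cambridge prognostic grouping.

    Tiers 3 and 4 follow the published strategy boundaries (group >= 3:
    GS >= 4+3, or GS 3+4 with PSA 10-20; group >= 4: GS >= 8, PSA > 20 or
    T >= T3).  The group-5 criteria come from the model's source study
    (grade group 5, T4, or at least two of {grade group 4, PSA > 20, T3})
    and can be overridden via ``group5_rule(df) -> bool array``.
    """
    df, scalar = _as_frame(records)
    _require(
        df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "gnana"
    )
    psa, gg, _, t_idx = _fields(df)
    t3 = (t_idx >= 6) & (t_idx <= 8)
    if group5_rule is not None:
        g5 = np.asarray(group5_rule(df), dtype=bool)
    else:
        g5 = (
            (gg == 5)
            | (t_idx == 9)
            | (((gg == 4).astype(int) + (psa > 20).astype(int) + t3.astype(int)) >= 2)
        )
    g4 = (gg == 4) | (psa > 20) | (t_idx >= 6)
    g3 = (gg == 3) | ((gg == 2) & (psa >= 10) & (psa <= 20))
    g2 = (gg == 2) | ((psa >= 10) & (psa <= 20))
    group = np.select([g5, g4, g3, g2], [5, 4, 3, 2], default=1)
    return _ret(group, scalar)


def classify_gnanapragasam(records, min_group: int = 3):
    """Scan when the Cambridge group is at least ``min_group`` (the
    published Strategy 1 uses 3, Strategy 2 uses 4; group-5-only is the
    third evaluated strategy)."""
    group = np.atleast_1d(gnanapragasam_group(records))
    scan = group >= min_group
    _, scalar = _as_frame(records)
    return _ret(scan, scalar)


def isup_grade_group(records):
    """ISUP grade group 1-5 of each record."""
    df, scalar = _as_frame(records)
    _require(df, ["gleason_primary", "gleason_secondary"], "isup")
    gg = grade_group(df["gleason_primary"], df["gleason_secondary"])
    return _ret(np.asarray(gg, dtype=float), scalar)


def classify_isup(records, min_grade_group: int = 3):
    """Scan when ISUP grade group is 3 or higher."""
    gg = np.atleast_1d(isup_grade_group(records))
    _, scalar = _as_frame(records)
    return _ret(gg >= min_grade_group, scalar)


def classify_simple_psa(records, threshold: float):
    """Scan when PSA strictly exceeds ``threshold`` (Lai, Chybowski)."""
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml"], "psa-threshold")
    psa = df["psa_ng_ml"].to_numpy(dtype=float)
    return _ret(psa > threshold, scalar)


def classify_ho(records):
    """Ho: scan when PSA > 10 or suspected nodal involvement on imaging."""
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml", "n_stage_positive"], "ho")
    psa = df["psa_ng_ml"].to_numpy(dtype=float)
    npos = df["n_stage_positive"].to_numpy(dtype=float) > 0
    return _ret((psa > 10) | npos, scalar)


def classify_osullivan(records):
    """O'Sullivan: scan when PSA > 20, T-stage 4, or GS >= 4+3."""
    df, scalar = _as_frame(records)
    _require(
        df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "osullivan"
    )
    psa, gg, _, t_idx = _fields(df)
    return _ret((psa > 20) | (t_idx == 9) | (gg >= 3), scalar)


def briganti_group(records):
    """Briganti CART risk group as low/intermediate/high.

    High is the published scan rule (GS >= 8 or PSA > 10 in T2-T3 disease,
    T2-T3 read as T2a-T3c inclusive); intermediate is GS 7 or PSA > 10
    outside the high tier; low otherwise."""
    df, scalar = _as_frame(records)
    _require(
        df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "briganti"
    )
    psa, _, gsum, t_idx = _fields(df)
    high = (gsum >= 8) | ((psa > 10) & (t_idx >= 3) & (t_idx <= 8))
    mid = ~high & ((gsum == 7) | (psa > 10))
    return _ret(np.select([high, mid], ["high", "intermediate"], default="low"), scalar)


def classify_briganti(records):
    """Scan when GS >= 8, or PSA > 10 in T2-T3 disease."""
    grp = np.atleast_1d(briganti_group(records))
    _, scalar = _as_frame(records)
    return _ret(grp == "high", scalar)


def lai_psa_group(records):
    """Lai PSA risk categories as ordinal 0-3 (<10, 10-20, 20-50, >50)."""
    df, scalar = _as_frame(records)
    _require(df, ["psa_ng_ml"], "lai")
    psa = df["psa_ng_ml"].to_numpy(dtype=float)
    return _ret(np.digitize(psa, [10.0, 20.0, 50.0]), scalar)


# ---------------------------------------------------------------------------
# registry

@dataclass
class RiskPrediction:
    """One model's prediction for one patient."""

    kind: str  # "continuous" | "categorical"
    risk_probability: float | None = None
    risk_group: object | None = None
    group_predicted_risk: float | None = None


@dataclass
class RiskModel:
    """A registered staging model.

    ``score`` maps a complete cohort frame to a risk-ordered numeric score
    (used for discrimination); ``risk`` to probabilities in (0,1) when a
    continuous form exists; ``group`` to ordered group labels for
    categorical/guideline models.  ``group_risks`` attaches development-study
    positivity rates to groups, giving categorical models a numeric
    predicted risk for calibration.
    """

    name: str
    kind: str  # "continuous" | "categorical" | "guideline"
    score: Callable[[pd.DataFrame], np.ndarray]
    strategies: dict[str, Callable[[pd.DataFrame], np.ndarray]] = field(
        default_factory=dict
    )
    recommended: str | None = None
    risk: Callable[[pd.DataFrame], np.ndarray] | None = None
    group: Callable[[pd.DataFrame], np.ndarray] | None = None
    group_risks: dict | None = None
    overall_rate: float | None = None

    def scores(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.score(df), dtype=float)

    def has_risk_form(self) -> bool:
        return self.risk is not None or (
            self.group is not None and self.group_risks is not None
        )

    def risks(self, df: pd.DataFrame) -> np.ndarray:
        """Numeric predicted risks in (0,1) for every record."""
        if self.risk is not None:
            return np.asarray(self.risk(df), dtype=float)
        if self.group is not None and self.group_risks is not None:
            groups = np.atleast_1d(self.group(df))
            out = np.empty(len(groups), dtype=float)
            for i, g in enumerate(groups):
                out[i] = self.group_predicted_risk(g)
            return out
        raise NoNumericRiskError(
            f"model {self.name!r} reports no numeric predicted risk"
        )

    def group_predicted_risk(self, group) -> float:
        """Development-study positivity rate configured for ``group``."""
        if self.group_risks is None:
            raise NoNumericRiskError(
                f"model {self.name!r} has no configured group risks"
            )
        key = group
        if key not in self.group_risks:
            # tolerate int/float/str key mismatches from YAML configs
            for cand in (str(group), int(group) if _intlike(group) else None):
                if cand is not None and cand in self.group_risks:
                    key = cand
                    break
            else:
                raise NoNumericRiskError(
                    f"model {self.name!r}: no development rate for group {group!r}"
                )
        rate = float(self.group_risks[key])
        if not (0.0 < rate < 1.0):
            raise ValueError(
                f"model {self.name!r}: configured rate {rate} outside (0, 1)"
            )
        return rate

    def predict(self, record) -> RiskPrediction:
        """Single-record prediction as a :class:`RiskPrediction`."""
        df, _ = _as_frame(record)
        if self.risk is not None:
            return RiskPrediction(
                kind="continuous", risk_probability=float(self.risks(df)[0])
            )
        if self.group is not None:
            g = np.atleast_1d(self.group(df))[0]
            rate = None
            if self.group_risks is not None:
                rate = self.group_predicted_risk(g)
            return RiskPrediction(
                kind="categorical", risk_group=g, group_predicted_risk=rate
            )
        raise FormUnavailableError(f"model {self.name!r} has no prediction form")


def _intlike(x) -> int | None:
    try:
        return int(x)
    except (TypeError, ValueError):
        return None


class ModelRegistry:
    """Name-addressable collection of :class:`RiskModel` objects."""

    def __init__(self) -> None:
        self._models: dict[str, RiskModel] = {}

    def register(self, model: RiskModel) -> None:
        if model.name in self._models:
            raise ValueError(f"duplicate model name {model.name!r}")
        for strat in model.strategies:
            if any(
                strat in m.strategies for m in self._models.values()
            ):
                raise ValueError(f"duplicate strategy name {strat!r}")
        if model.recommended is not None and model.recommended not in model.strategies:
            raise ValueError(
                f"recommended strategy {model.recommended!r} not in {model.name!r}"
            )
        self._models[model.name] = model

    def __getitem__(self, name: str) -> RiskModel:
        try:
            return self._models[name]
        except KeyError:
            raise KeyError(f"unregistered model {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._models

    def __iter__(self):
        return iter(self._models.values())

    def names(self) -> list[str]:
        return list(self._models)

    def strategies(self):
        """Yield (strategy_name, model_name, predicate) over all models."""
        for model in self:
            for strat, fn in model.strategies.items():
                yield strat, model.name, fn

    def strategy(self, strategy_name: str):
        for strat, model_name, fn in self.strategies():
            if strat == strategy_name:
                return model_name, fn
        raise KeyError(f"unknown strategy {strategy_name!r}")

    def predict_continuous(self, model_name: str, records) -> np.ndarray:
        """Probability predictions; raises :class:`FormUnavailableError`
        when the model has no registered probability form (never a silent
        fallback)."""
        model = self[model_name]
        if not model.has_risk_form():
            raise FormUnavailableError(
                f"no continuous probability form registered for {model_name!r}"
            )
        df, scalar = _as_frame(records)
        risks = model.risks(df)
        return _ret(risks, scalar)


def _interp_curve(table: list) -> Callable[[pd.DataFrame], np.ndarray]:
    xs = np.array([float(r[0]) for r in table])
    ps = np.array([float(r[1]) for r in table])
    order = np.argsort(xs)
    xs, ps = xs[order], ps[order]
    if np.any((ps <= 0) | (ps >= 1)):
        raise ValueError("lookup-table probabilities must lie in (0, 1)")

    def fn(df: pd.DataFrame) -> np.ndarray:
        _require(df, ["psa_ng_ml"], "chybowski")
        return np.interp(df["psa_ng_ml"].to_numpy(dtype=float), xs, ps)

    return fn


def _ho_logistic(coefs: Mapping[str, float]) -> Callable[[pd.DataFrame], np.ndarray]:
    def fn(df: pd.DataFrame) -> np.ndarray:
        _require(df, ["psa_ng_ml", "n_stage_positive"], "ho")
        lp = (
            coefs["intercept"]
            + coefs["ln_psa"] * np.log(df["psa_ng_ml"].to_numpy(dtype=float))
            + coefs["n_stage_positive"]
            * (df["n_stage_positive"].to_numpy(dtype=float) > 0)
        )
        return expit(lp)

    return fn


#: Overall development-study positivity rates (documented placeholders;
#: per-group rates must come from user configuration).
DEV_POSITIVITY = {
    "chybowski": 0.14,
    "osullivan": 0.16,
    "briganti": 0.03,
    "lai": 0.29,
    "ho": 0.36,
    "wang": 0.13,
    "gnanapragasam": 0.08,
    "isup": 0.08,
}


def default_registry(
    group_risks: Mapping[str, Mapping] | None = None,
    chybowski_curve: list | None = None,
    ho_coefficients: Mapping[str, float] | None = None,
    wang_invert: bool = False,
) -> ModelRegistry:
    """The eleven validated models with their published strategies.

    ``group_risks`` maps model name -> {group: development positivity rate}
    to endow categorical models with numeric predicted risks;
    ``chybowski_curve`` is a PSA->probability lookup table (list of pairs)
    and ``ho_coefficients`` a logistic form {intercept, ln_psa,
    n_stage_positive} — neither is printed in the validation source, so
    without user configuration only the fixed strategies of those models
    are available.
    """
    group_risks = dict(group_risks or {})
    reg = ModelRegistry()

    def _gr(name):
        return dict(group_risks[name]) if name in group_risks else None

    def _wang_df(df):
        _require(
            df, ["psa_ng_ml", "t_stage", "gleason_primary", "gleason_secondary"], "wang"
        )
        return np.atleast_1d(
            wang_score(
                df["psa_ng_ml"],
                df["t_stage"],
                df["gleason_primary"],
                df["gleason_secondary"],
            )
        )

    reg.register(
        RiskModel(
            name="wang",
            kind="continuous",
            score=_wang_df,
            risk=lambda df: expit(_wang_df(df)),
            strategies={"wang-d": lambda df: classify_wang(df, invert=wang_invert)},
            recommended="wang-d",
            overall_rate=DEV_POSITIVITY["wang"],
        )
    )

    def _psa_score(df):
        _require(df, ["psa_ng_ml"], "psa")
        return df["psa_ng_ml"].to_numpy(dtype=float)

    reg.register(
        RiskModel(
            name="chybowski",
            kind="continuous",
            score=_psa_score,
            risk=_interp_curve(chybowski_curve) if chybowski_curve else None,
            strategies={
                "chybowski-psa10": lambda df: classify_simple_psa(df, 10.0),
                "chybowski-psa20": lambda df: classify_simple_psa(df, 20.0),
            },
            recommended="chybowski-psa10",
            overall_rate=DEV_POSITIVITY["chybowski"],
        )
    )

    def _ho_score(df):
        # nodal-positive patients rank above all others, then by PSA
        _require(df, ["psa_ng_ml", "n_stage_positive"], "ho")
        psa = df["psa_ng_ml"].to_numpy(dtype=float)
        npos = df["n_stage_positive"].to_numpy(dtype=float) > 0
        return psa + 1e4 * npos

    reg.register(
        RiskModel(
            name="ho",
            kind="continuous",
            score=_ho_score,
            risk=_ho_logistic(ho_coefficients) if ho_coefficients else None,
            strategies={"ho-psa10-or-node": classify_ho},
            recommended="ho-psa10-or-node",
            overall_rate=DEV_POSITIVITY["ho"],
        )
    )

    reg.register(
        RiskModel(
            name="lai",
            kind="categorical",
            score=lambda df: np.atleast_1d(lai_psa_group(df)).astype(float),
            group=lambda df: np.atleast_1d(lai_psa_group(df)),
            group_risks=_gr("lai"),
            strategies={"lai-psa10": lambda df: classify_simple_psa(df, 10.0)},
            recommended="lai-psa10",
            overall_rate=DEV_POSITIVITY["lai"],
        )
    )

    reg.register(
        RiskModel(
            name="osullivan",
            kind="categorical",
            score=lambda df: np.atleast_1d(classify_osullivan(df)).astype(float),
            group=lambda df: np.where(
                np.atleast_1d(classify_osullivan(df)), "high", "low"
            ),
            group_risks=_gr("osullivan"),
            strategies={"osullivan": classify_osullivan},
            recommended="osullivan",
            overall_rate=DEV_POSITIVITY["osullivan"],
        )
    )

    _BRIG_ORD = {"low": 0, "intermediate": 1, "high": 2}
    reg.register(
        RiskModel(
            name="briganti",
            kind="categorical",
            score=lambda df: np.array(
                [_BRIG_ORD[g] for g in np.atleast_1d(briganti_group(df))], dtype=float
            ),
            group=lambda df: np.atleast_1d(briganti_group(df)),
            group_risks=_gr("briganti"),
            strategies={"briganti": classify_briganti},
            recommended="briganti",
            overall_rate=DEV_POSITIVITY["briganti"],
        )
    )

    reg.register(
        RiskModel(
            name="gnanapragasam",
            kind="categorical",
            score=lambda df: np.atleast_1d(gnanapragasam_group(df)).astype(float),
            group=lambda df: np.atleast_1d(gnanapragasam_group(df)),
            group_risks=_gr("gnanapragasam"),
            strategies={
                "gnana-group3": lambda df: classify_gnanapragasam(df, 3),
                "gnana-group4": lambda df: classify_gnanapragasam(df, 4),
                "gnana-group5": lambda df: classify_gnanapragasam(df, 5),
            },
            recommended="gnana-group3",
            overall_rate=DEV_POSITIVITY["gnanapragasam"],
        )
    )

    reg.register(
        RiskModel(
            name="isup",
            kind="categorical",
            score=lambda df: np.atleast_1d(isup_grade_group(df)).astype(float),
            group=lambda df: np.atleast_1d(isup_grade_group(df)).astype(int),
            group_risks=_gr("isup"),
            strategies={"isup-gg3": classify_isup},
            recommended="isup-gg3",
            overall_rate=DEV_POSITIVITY["isup"],
        )
    )

    reg.register(
        RiskModel(
            name="eau",
            kind="guideline",
            score=lambda df: np.atleast_1d(eau_risk_stratum(df)).astype(float),
            group=lambda df: np.atleast_1d(eau_risk_stratum(df)),
            strategies={
                "eau-2020": classify_eau,
                "eau-high-only": classify_eau_high_risk,
            },
            recommended="eau-2020",
        )
    )

    reg.register(
        RiskModel(
            name="aua",
            kind="guideline",
            score=lambda df: np.atleast_1d(aua_risk_stratum(df)).astype(float),
            group=lambda df: np.atleast_1d(aua_risk_stratum(df)),
            strategies={"aua-2018": classify_aua},
            recommended="aua-2018",
        )
    )

    reg.register(
        RiskModel(
            name="nccn",
            kind="guideline",
            score=lambda df: np.atleast_1d(nccn_risk_stratum(df)).astype(float),
            group=lambda df: np.atleast_1d(nccn_risk_stratum(df)),
            strategies={"nccn-2019": classify_nccn},
            recommended="nccn-2019",
        )
    )

    return reg


def load_registry_config(path) -> ModelRegistry:
    """Build a registry from a YAML config.

    Recognised keys: ``group_risks`` (model -> {group: rate}),
    ``chybowski_curve`` (list of [psa, probability] pairs),
    ``ho_coefficients`` ({intercept, ln_psa, n_stage_positive}),
    ``wang_invert`` (bool).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return default_registry(
        group_risks=raw.get("group_risks"),
        chybowski_curve=raw.get("chybowski_curve"),
        ho_coefficients=raw.get("ho_coefficients"),
        wang_invert=bool(raw.get("wang_invert", False)),
    )
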