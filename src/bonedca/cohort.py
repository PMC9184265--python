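"""Synthetic prostate-cancer registry cohorts.

Generates patient-level tables with the statistical structure a selective
bone-scan staging analysis assumes: realistic predictor marginals (PSA,
Gleason pattern, clinical T-stage, percent positive biopsy cores, nodal
stage), a latent logistic model for bone-scan positivity, exponential
survival with a hazard differential by positivity, and missing-at-random
masking driven by treatment setting and risk stratum (the two mechanisms a
registry exhibits: selective scanning of higher-risk patients, and data
restriction in privately treated patients).

Every run keeps a parallel *truth table* holding the pre-masking values and
the latent positivity status, so downstream imputation and validation code
can be tested as parameter-recovery experiments.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "T_STAGES",
    "GeneratorConfig",
    "CohortBundle",
    "ConfigError",
    "CohortDataError",
    "generate_cohort",
    "flag_staging_scans",
    "reclassify_indeterminate",
    "write_cohort",
    "read_cohort",
]

#: Ordered clinical T-stage categories, least to most extensive.
T_STAGES = ["T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T3c", "T4"]

#: Canonical cohort column order.
COLUMNS = [
    "patient_id",
    "age_years",
    "psa_ng_ml",
    "gleason_primary",
    "gleason_secondary",
    "pct_pos_cores",
    "t_stage",
    "n_stage_positive",
    "scan_result",
    "scan_offset_days",
    "treatment_setting",
    "survival_months",
    "dead",
    "year_of_diagnosis",
]

SCAN_RESULTS = ("positive", "negative", "indeterminate", "none")


class ConfigError(ValueError):
    """Invalid generator or pipeline configuration."""


class CohortDataError(ValueError):
    """Cohort table violates a structural precondition."""


def _default_gleason_probs() -> dict[str, float]:
    # Marginals match a registry where ~36% are Gleason <=6, ~27% 3+4,
    # ~16% 4+3 and ~21% Gleason 8-10.
    return {
        "3+3": 0.365,
        "3+4": 0.265,
        "4+3": 0.162,
        "4+4": 0.120,
        "4+5": 0.058,
        "5+4": 0.020,
        "5+5": 0.010,
    }


def _default_t_stage_probs() -> dict[str, float]:
    # ~64% T1, ~29% T2, ~5% T3, ~3% T4 among staged patients.
    return {
        "T1a": 0.020,
        "T1b": 0.020,
        "T1c": 0.596,
        "T2a": 0.150,
        "T2b": 0.080,
        "T2c": 0.057,
        "T3a": 0.035,
        "T3b": 0.013,
        "T3c": 0.003,
        "T4": 0.026,
    }


def _default_risk_coefficients() -> dict[str, float | None]:
    # Log-odds of bone-scan positivity; intercept None means "calibrate at
    # generation time so the positivity rate among scanned patients hits
    # target_positivity_among_scanned".
    return {
        "intercept": None,
        "ln_psa": 1.10,
        "grade_group": 0.55,
        "t_index": 0.22,
        "pct_cores": 0.008,
    }


def _default_scan_probs() -> dict[str, dict[str, float]]:
    # P(staging scan on record | risk stratum, treatment setting).  Private
    # records are less complete; high-risk patients are scanned more.
    return {
        "low": {"public": 0.18, "private": 0.10},
        "intermediate": {"public": 0.42, "private": 0.26},
        "high": {"public": 0.62, "private": 0.45},
    }


def _default_missingness() -> dict[str, dict[str, float]]:
    # "rate" is the marginal missingness fraction the masking converges to;
    # the multipliers tilt it toward private-setting and low-risk patients
    # (MAR given setting and risk stratum) while the normalisation in
    # _mask_missing keeps the marginal at "rate".
    return {
        "psa_ng_ml": {"rate": 0.401, "private_mult": 1.5, "low_risk_mult": 1.3},
        "t_stage": {"rate": 0.766, "private_mult": 1.2, "low_risk_mult": 1.1},
        "gleason": {"rate": 0.024, "private_mult": 1.5, "low_risk_mult": 1.0},
        "pct_pos_cores": {"rate": 0.171, "private_mult": 1.4, "low_risk_mult": 1.2},
        "n_stage_positive": {"rate": 0.760, "private_mult": 1.2, "low_risk_mult": 1.1},
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic registry.

    Defaults target the marginals of a population-based staging cohort:
    ~38% of patients with a staging scan on record, ~8.7% positivity among
    scanned, ~3.7% indeterminate scans, PSA median ~8 ng/mL, and per-variable
    missingness of 40.1% (PSA), 76.6% (T-stage), 2.4% (Gleason), 17.1%
    (cores) and 76.0% (nodal stage).
    """

    n_patients: int = 2000
    seed: int = 0

    # predictor distributions
    age_mean: float = 67.9
    age_sd: float = 9.0
    age_range: tuple[float, float] = (34.0, 98.0)
    psa_log_mu: float = 2.10
    psa_log_sigma: float = 0.55
    psa_tail_frac: float = 0.06
    psa_tail_log_mu: float = 4.0
    psa_tail_log_sigma: float = 0.9
    gleason_probs: dict[str, float] = field(default_factory=_default_gleason_probs)
    t_stage_probs: dict[str, float] = field(default_factory=_default_t_stage_probs)
    cores_beta_a: float = 1.4
    cores_beta_b: float = 2.4
    private_frac: float = 0.45
    year_range: tuple[int, int] = (2005, 2019)

    # latent positivity model
    risk_coefficients: dict[str, float | None] = field(
        default_factory=_default_risk_coefficients
    )
    target_positivity_among_scanned: float = 0.087

    # nodal stage conditional on true bone positivity
    n_pos_prob_given_positive: float = 0.45
    n_pos_prob_given_negative: float = 0.035

    # scan availability / timing
    scan_probs: dict[str, dict[str, float]] = field(default_factory=_default_scan_probs)
    indeterminate_rate: float = 0.037
    indeterminate_resolved_frac: float = 0.90
    late_scan_frac: float = 0.05

    # survival (exponential, per-month hazards)
    hazard_negative_per_month: float = 0.0021
    hazard_ratio_positive: float = 5.5

    # MAR masking
    missingness: dict[str, dict[str, float]] = field(default_factory=_default_missingness)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        probs = [
            self.psa_tail_frac,
            self.private_frac,
            self.indeterminate_rate,
            self.indeterminate_resolved_frac,
            self.late_scan_frac,
            self.target_positivity_among_scanned,
            self.n_pos_prob_given_positive,
            self.n_pos_prob_given_negative,
        ]
        probs += list(self.gleason_probs.values())
        probs += list(self.t_stage_probs.values())
        for d in self.scan_probs.values():
            probs += list(d.values())
        for d in self.missingness.values():
            probs.append(d["rate"])
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p!r} outside [0, 1]")
        if abs(sum(self.gleason_probs.values()) - 1.0) > 1e-6:
            raise ConfigError("gleason_probs must sum to 1")
        if abs(sum(self.t_stage_probs.values()) - 1.0) > 1e-6:
            raise ConfigError("t_stage_probs must sum to 1")
        if self.hazard_negative_per_month <= 0 or self.hazard_ratio_positive <= 0:
            raise ConfigError("hazards must be positive")

    # -- structured-text round trip -------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("age_range", "year_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class CohortBundle:
    """A generated cohort plus its ground truth.

    cohort            masked table as an analyst would receive it
    truth             pre-masking values plus latent risk / true positivity
    followup_labels   resolved follow-up calls for a subset of indeterminate
                      scans (patient_id -> "positive"/"negative")
    resolved_intercept  the latent-model intercept actually used
    """

    cohort: pd.DataFrame
    truth: pd.DataFrame
    followup_labels: dict[str, str]
    config: GeneratorConfig
    resolved_intercept: float


def grade_group(primary, secondary):
    """ISUP grade group 1-5 from a Gleason primary+secondary pattern.

    Vectorised; NaN in, NaN out.
    """
    p = np.asarray(primary, dtype=float)
    s = np.asarray(secondary, dtype=float)
    total = p + s
    gg = np.full(np.broadcast(p, s).shape, np.nan)
    gg = np.where(total <= 6, 1.0, gg)
    gg = np.where((p == 3) & (s == 4), 2.0, gg)
    gg = np.where((p == 4) & (s == 3), 3.0, gg)
    gg = np.where(total == 8, 4.0, gg)
    gg = np.where(total >= 9, 5.0, gg)
    gg = np.where(np.isnan(p) | np.isnan(s), np.nan, gg)
    if np.ndim(primary) == 0 and np.ndim(secondary) == 0:
        return float(gg)
    return gg


def t_stage_index(t_stage):
    """Ordinal index 0-9 of a T-stage label (T1a..T4); NaN for missing."""
    mapping = {t: i for i, t in enumerate(T_STAGES)}
    if isinstance(t_stage, str):
        return float(mapping[t_stage])
    ser = pd.Series(t_stage)
    return ser.map(mapping).to_numpy(dtype=float)


def _risk_stratum(psa, gg, t_idx) -> np.ndarray:
    """Three-level clinical risk stratum used by the scan-availability and
    masking mechanisms (computed from true, pre-masking values)."""
    high = (psa > 20) | (gg >= 4) | (t_idx >= 6)
    low = ~high & (psa < 10) & (gg == 1) & (t_idx <= 3)
    out = np.where(high, "high", np.where(low, "low", "intermediate"))
    return out


def latent_linear_predictor(
    psa, gg, t_idx, cores, coefficients: Mapping[str, float | None]
) -> np.ndarray:
    """Latent log-odds of bone-scan positivity, without the intercept."""
    return (
        coefficients["ln_psa"] * np.log(psa)
        + coefficients["grade_group"] * (gg - 1.0)
        + coefficients["t_index"] * t_idx
        + coefficients["pct_cores"] * cores
    )


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate one synthetic registry cohort.

    Deterministic given ``config`` (including its seed): the master seed is
    split into named substreams (predictors, scan assignment, survival,
    masking) so each stage is independently reproducible.
    """
    config.validate()
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(4)
    rng_pred = np.random.default_rng(kids[0])   # predictors
    rng_scan = np.random.default_rng(kids[1])   # scan assignment + outcome
    rng_surv = np.random.default_rng(kids[2])   # survival
    rng_mask = np.random.default_rng(kids[3])   # MAR masking + follow-up

    # ---- predictors -----------------------------------------------------
    age = np.clip(
        rng_pred.normal(config.age_mean, config.age_sd, n), *config.age_range
    ).round(1)
    setting = np.where(
        rng_pred.random(n) < config.private_frac, "private", "public"
    )
    year = rng_pred.integers(config.year_range[0], config.year_range[1] + 1, n)

    patterns = list(config.gleason_probs)
    pk = rng_pred.choice(len(patterns), size=n, p=list(config.gleason_probs.values()))
    gp = np.array([int(patterns[i].split("+")[0]) for i in pk], dtype=float)
    gs = np.array([int(patterns[i].split("+")[1]) for i in pk], dtype=float)
    gg = grade_group(gp, gs)

    tail = rng_pred.random(n) < config.psa_tail_frac
    psa = np.where(
        tail,
        rng_pred.lognormal(config.psa_tail_log_mu, config.psa_tail_log_sigma, n),
        rng_pred.lognormal(config.psa_log_mu, config.psa_log_sigma, n),
    ).round(2)
    psa = np.maximum(psa, 0.01)

    tstage_labels = list(config.t_stage_probs)
    tk = rng_pred.choice(
        len(tstage_labels), size=n, p=list(config.t_stage_probs.values())
    )
    t_stage = np.array([tstage_labels[i] for i in tk])
    t_idx = t_stage_index(pd.Series(t_stage))

    cores = (100.0 * rng_pred.beta(config.cores_beta_a, config.cores_beta_b, n)).round(2)

    stratum = _risk_stratum(psa, gg, t_idx)

    # ---- scan availability ----------------------------------------------
    p_scan = np.array(
        [config.scan_probs[st][se] for st, se in zip(stratum, setting)]
    )
    scanned = rng_scan.random(n) < p_scan

    # ---- latent positivity ----------------------------------------------
    lp0 = latent_linear_predictor(psa, gg, t_idx, cores, config.risk_coefficients)
    intercept = config.risk_coefficients.get("intercept")
    if intercept is None:
        if not scanned.any():
            raise ConfigError(
                "cannot calibrate positivity intercept: no scanned patients"
            )
        target = config.target_positivity_among_scanned
        sub = lp0[scanned]

        def gap(c: float) -> float:
            return float(np.mean(expit(sub + c))) - target

        intercept = brentq(gap, -40.0, 20.0)
    intercept = float(intercept)
    with np.errstate(over="ignore"):
        risk = expit(lp0 + intercept)
    true_pos = rng_scan.random(n) < risk

    n_pos = np.where(
        true_pos,
        rng_scan.random(n) < config.n_pos_prob_given_positive,
        rng_scan.random(n) < config.n_pos_prob_given_negative,
    ).astype(float)

    # ---- scan result + offset -------------------------------------------
    late = rng_scan.random(n) < config.late_scan_frac
    offset = np.where(
        late,
        rng_scan.integers(141, 366, n),
        rng_scan.integers(0, 141, n),
    ).astype(float)
    offset[~scanned] = np.nan

    indet = scanned & (rng_scan.random(n) < config.indeterminate_rate)
    scan_result = np.full(n, "none", dtype=object)
    scan_result[scanned & true_pos] = "positive"
    scan_result[scanned & ~true_pos] = "negative"
    scan_result[indet] = "indeterminate"

    # ---- survival --------------------------------------------------------
    hazard = config.hazard_negative_per_month * np.where(
        true_pos, config.hazard_ratio_positive, 1.0
    )
    event_time = rng_surv.exponential(1.0 / hazard, n)
    followup = (config.year_range[1] + 0.4 - year) * 12.0 + rng_surv.uniform(0, 12, n)
    followup = np.maximum(followup, 1.0)
    dead = event_time < followup
    survival = np.minimum(event_time, followup).round(2)

    ids = np.array([f"P{i:06d}" for i in range(n)])
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "age_years": age,
            "psa_ng_ml": psa,
            "gleason_primary": gp,
            "gleason_secondary": gs,
            "pct_pos_cores": cores,
            "t_stage": t_stage,
            "n_stage_positive": n_pos,
            "scan_result": scan_result.copy(),
            "scan_offset_days": offset,
            "treatment_setting": setting,
            "survival_months": survival,
            "dead": dead,
            "year_of_diagnosis": year,
            "true_scan_positive": true_pos,
            "latent_risk": risk,
            "risk_stratum": stratum,
            "scanned": scanned,
        }
    )

    cohort = truth[COLUMNS].copy()

    # ---- MAR masking -----------------------------------------------------
    is_private = (setting == "private").astype(float)
    is_low = (stratum == "low").astype(float)
    for var, pars in config.missingness.items():
        mult = pars["private_mult"] ** is_private * pars["low_risk_mult"] ** is_low
        p_miss = np.clip(pars["rate"] * mult / mult.mean(), 0.0, 1.0)
        mask = rng_mask.random(n) < p_miss
        if var == "gleason":
            cohort.loc[mask, ["gleason_primary", "gleason_secondary"]] = np.nan
        else:
            cohort.loc[mask, var] = np.nan

    # ---- follow-up resolutions for indeterminate scans -------------------
    followup_labels: dict[str, str] = {}
    for i in np.flatnonzero(indet):
        if rng_mask.random() < config.indeterminate_resolved_frac:
            followup_labels[ids[i]] = "positive" if true_pos[i] else "negative"

    return CohortBundle(
        cohort=cohort,
        truth=truth,
        followup_labels=followup_labels,
        config=config,
        resolved_intercept=intercept,
    )


def flag_staging_scans(records: pd.DataFrame, window_days: int = 140) -> pd.DataFrame:
    """Keep only scans performed within ``window_days`` of diagnosis as
    staging scans (inclusive boundary: a scan on day ``window_days`` counts).

    Later scans are reclassified ``scan_result = "none"`` and lose their
    offset, so downstream stages treat them as unscanned.
    """
    if window_days <= 0:
        raise ConfigError("window_days must be positive")
    out = records.copy()
    offsets = out["scan_offset_days"]
    if (offsets.dropna() < 0).any():
        raise CohortDataError("negative scan offsets")
    late = (out["scan_result"] != "none") & (offsets > window_days)
    out.loc[late, "scan_result"] = "none"
    out.loc[late, "scan_offset_days"] = np.nan
    return out


def reclassify_indeterminate(
    records: pd.DataFrame, followup_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Resolve indeterminate scans with follow-up calls.

    Labelled indeterminates become positive/negative; unlabelled ones become
    ``none`` (left for imputation).  Supplying a label for a patient whose
    scan is not indeterminate is a data error.
    """
    out = records.copy()
    indet_ids = set(out.loc[out["scan_result"] == "indeterminate", "patient_id"])
    for pid, label in followup_labels.items():
        if label not in ("positive", "negative"):
            raise CohortDataError(f"invalid follow-up label {label!r} for {pid}")
        if pid not in indet_ids:
            raise CohortDataError(
                f"follow-up label supplied for non-indeterminate patient {pid}"
            )
    idx = out["patient_id"].map(dict(followup_labels))
    resolved = idx.notna() & (out["scan_result"] == "indeterminate")
    out.loc[resolved, "scan_result"] = idx[resolved]
    unresolved = out["scan_result"] == "indeterminate"
    out.loc[unresolved, "scan_result"] = "none"
    out.loc[unresolved, "scan_offset_days"] = np.nan
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O

def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort (or truth) table as CSV with "" for missing cells."""
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in ("dead", "true_scan_positive", "scanned"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    return df
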