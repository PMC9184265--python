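"""End-to-end orchestration: cohort -> staging-scan window -> indeterminate
resolution -> multiple imputation -> model validation -> decision curves ->
optimal-strategy map, with every output as delimited text.

The run is deterministic under its master seed: the seed is split into
named substreams for cohort generation and imputation, and all output
tables are written with a fixed float format.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortBundle,
    ConfigError,
    GeneratorConfig,
    flag_staging_scans,
    generate_cohort,
    read_cohort,
    reclassify_indeterminate,
    write_cohort,
)
from .dca import (
    all_strategy_curves,
    default_grid,
    optimal_strategy_map,
    recommended_vs_best_table,
)
from .impute import mice_impute
from .metrics import pooled_validation
from .models import ModelRegistry, default_registry

__all__ = [
    "RunConfig",
    "RunResult",
    "PipelineError",
    "run_pipeline",
    "summarize_cohort",
    "percent",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def percent(numerator: float, denominator: float, decimals: int = 1,
            truncate: bool = False) -> float:
    """Percentage with half-up rounding (the reporting convention), or
    truncation toward zero under ``truncate=True``."""
    if denominator == 0:
        raise ValueError("zero denominator")
    value = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    mode = ROUND_FLOOR if truncate else ROUND_HALF_UP
    return float(value.quantize(quantum, rounding=mode))


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one of ``generator``/``cohort_path``."""

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    out_dir: str = "bonedca-run"
    seed: int = 0
    m: int = 5
    iterations: int = 10
    window_days: int = 140
    models: list[str] | None = None  # None = all registered
    grid: tuple[float, float, float] = (0.01, 0.10, 0.001)
    registry_config: str | None = None
    verbosity: str = "info"

    def validate(self, registry: ModelRegistry) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise ConfigError("exactly one of generator/cohort_path must be set")
        lo, hi, step = self.grid
        if not (0 < lo < hi < 1) or step <= 0:
            raise ConfigError("grid bounds must satisfy 0 < lo < hi < 1, step > 0")
        if self.m < 1 or self.iterations < 1:
            raise ConfigError("m and iterations must be >= 1")
        if self.models is not None:
            for name in self.models:
                if name not in registry:
                    raise ConfigError(f"unregistered model {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "grid"})
        if "grid" in raw:
            cfg.grid = tuple(raw["grid"])
        if gen is not None:
            for key in ("age_range", "year_range"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            cfg.generator = GeneratorConfig(**gen)
        return cfg


@dataclass
class RunResult:
    out_dir: Path
    cohort_summary: pd.DataFrame
    validation: pd.DataFrame
    curves: pd.DataFrame
    optimal_map: pd.DataFrame
    recommended_vs_best: pd.DataFrame
    manifest: dict


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pre-imputation characteristics table: per-variable missingness and
    medians/IQRs or counts, stratified by staging-scan result."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    strata = {
        "overall": np.ones(len(cohort), dtype=bool),
        "negative": (cohort["scan_result"] == "negative").to_numpy(),
        "positive": (cohort["scan_result"] == "positive").to_numpy(),
        "no_scan": (~cohort["scan_result"].isin(["negative", "positive"])).to_numpy(),
    }
    rows = []

    def add(variable, statistic, values):
        rows.append({"variable": variable, "statistic": statistic, **values})

    add("n", "count", {k: int(m.sum()) for k, m in strata.items()})
    n_scanned = int((strata["negative"] | strata["positive"]).sum())
    n_pos = int(strata["positive"].sum())
    add(
        "scan_positivity",
        "percent_of_scanned",
        {
            "overall": percent(n_pos, n_scanned) if n_scanned else np.nan,
            "negative": np.nan,
            "positive": np.nan,
            "no_scan": np.nan,
        },
    )
    for var in ("age_years", "psa_ng_ml", "pct_pos_cores", "survival_months"):
        col = cohort[var].astype(float)
        add(
            var,
            "median",
            {k: float(col[m].median()) if m.any() else np.nan for k, m in strata.items()},
        )
        add(
            var,
            "iqr_low",
            {
                k: float(col[m].quantile(0.25)) if m.any() else np.nan
                for k, m in strata.items()
            },
        )
        add(
            var,
            "iqr_high",
            {
                k: float(col[m].quantile(0.75)) if m.any() else np.nan
                for k, m in strata.items()
            },
        )
    for var in (
        "psa_ng_ml",
        "t_stage",
        "gleason_primary",
        "pct_pos_cores",
        "n_stage_positive",
    ):
        miss = cohort[var].isna().to_numpy()
        add(
            var,
            "missing_pct",
            {
                k: percent(int((miss & m).sum()), int(m.sum())) if m.any() else np.nan
                for k, m in strata.items()
            },
        )
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def run_pipeline(config: RunConfig, registry: ModelRegistry | None = None) -> RunResult:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Outputs: cohort.csv (+ truth.csv for synthetic runs), cohort_summary.csv,
    validation.csv, curves.csv, optimal_map.csv, recommended_vs_best.csv,
    manifest.json and run.log.  Any stage error aborts with a stage-labelled
    message and removes partial outputs.
    """
    if registry is None:
        registry = default_registry()
    config.validate(registry)
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bonedca")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))

    stage = "setup"
    try:
        master = np.random.SeedSequence(config.seed)
        sub = master.spawn(2)
        gen_seed = int(sub[0].generate_state(1)[0] % (2**31))
        imp_seed = int(sub[1].generate_state(1)[0] % (2**31))

        stage = "cohort"
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=gen_seed)
            bundle = generate_cohort(gen)
            cohort = bundle.cohort
            followup = bundle.followup_labels
            write_cohort(bundle.truth, out / "truth.csv")
            logger.info("generated synthetic cohort n=%d", len(cohort))
        else:
            cohort = read_cohort(config.cohort_path)
            followup = {}
            logger.info("loaded cohort n=%d from %s", len(cohort), config.cohort_path)

        stage = "staging-window"
        cohort = flag_staging_scans(cohort, window_days=config.window_days)
        followup = {
            pid: lab
            for pid, lab in followup.items()
            if pid
            in set(
                cohort.loc[cohort["scan_result"] == "indeterminate", "patient_id"]
            )
        }
        cohort = reclassify_indeterminate(cohort, followup)
        write_cohort(cohort, out / "cohort.csv")

        stage = "summary"
        summary = summarize_cohort(cohort)
        _write_csv(summary, out / "cohort_summary.csv")

        stage = "imputation"
        imputed = mice_impute(
            cohort, m=config.m, iterations=config.iterations, seed=imp_seed
        )
        logger.info("imputed m=%d datasets, %d sweeps each", config.m, config.iterations)

        stage = "validation"
        validation = pooled_validation(imputed, registry)
        _write_csv(validation, out / "validation.csv")

        stage = "decision-curves"
        grid = default_grid(*config.grid)
        curves = all_strategy_curves(
            registry, imputed, grid=grid, models=config.models
        )
        curves_df = pd.concat([c.to_frame() for c in curves], ignore_index=True)
        _write_csv(curves_df, out / "curves.csv")

        omap = optimal_strategy_map(curves)
        omap_df = omap.to_frame()
        _write_csv(omap_df, out / "optimal_map.csv")

        rvb = recommended_vs_best_table(
            registry, imputed, grid=grid, models=config.models
        )
        _write_csv(rvb, out / "recommended_vs_best.csv")

        stage = "manifest"
        cfg_dict = dataclasses.asdict(config)
        cfg_dict.pop("out_dir", None)  # location, not an analysis parameter
        if cfg_dict.get("generator"):
            for key in ("age_range", "year_range"):
                cfg_dict["generator"][key] = list(cfg_dict["generator"][key])
        cfg_dict["grid"] = list(cfg_dict["grid"])
        cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
        manifest = {
            "package": "bonedca",
            "version": __version__,
            "seed": config.seed,
            "derived_seeds": {"generator": gen_seed, "imputation": imp_seed},
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for f in (
                "cohort.csv",
                "truth.csv",
                "cohort_summary.csv",
                "validation.csv",
                "curves.csv",
                "optimal_map.csv",
                "recommended_vs_best.csv",
                "manifest.json",
            ):
                (out / f).unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    finally:
        if handler in root.handlers:
            root.removeHandler(handler)
            handler.close()

    return RunResult(
        out_dir=out,
        cohort_summary=summary,
        validation=validation,
        curves=curves_df,
        optimal_map=omap_df,
        recommended_vs_best=rvb,
        manifest=manifest,
    )
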