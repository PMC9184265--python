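"""Decision-curve analysis: net benefit, preference ratios and the
number-willing-to-test (NWT) axis, fixed-strategy and continuous-model
curves, the optimal-strategy map, and recommended-vs-best comparison.

Net benefit of a scan/no-scan rule at threshold probability p_t is

    NB = TP/n - FP/n * p_t / (1 - p_t)

where TP and FP count scanned patients with and without a positive bone
scan.  A preference ratio a:b restates p_t = a/(a+b); NWT = 1/p_t is the
number of patients one is willing to scan to capture one positive scan
(displayed as floor(1/p_t)).  The default grid spans p_t 0.01-0.10 in
steps of 0.001, i.e. preference ratios 1:99 through 1:9 (NWT 100 down
to 10).

Curves are pooled across imputed datasets by the simple mean: counts are
linear, so the mean of per-dataset net benefits equals the net benefit of
the mean counts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .impute import ImputedCohortSet
from .models import FormUnavailableError, ModelRegistry, RiskModel

__all__ = [
    "PreferencePoint",
    "NetBenefitCurve",
    "OptimalStrategyMap",
    "default_grid",
    "ratio_to_pt",
    "pt_to_nwt",
    "net_benefit",
    "fixed_strategy_curve",
    "continuous_model_curve",
    "scan_all_curve",
    "scan_none_curve",
    "all_strategy_curves",
    "optimal_strategy_map",
    "recommended_vs_best_table",
]


def default_grid(lo: float = 0.01, hi: float = 0.10, step: float = 0.001) -> np.ndarray:
    """Threshold-probability grid, inclusive of both ends."""
    n = int(round((hi - lo) / step))
    grid = np.round(lo + step * np.arange(n + 1), 10)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid bounds must lie strictly inside (0, 1)")
    return grid


def ratio_to_pt(a: float, b: float) -> float:
    """Threshold probability of preference ratio a:b, p_t = a / (a + b)."""
    if a <= 0 or b <= 0:
        raise ValueError("preference-ratio components must be positive")
    return a / (a + b)


def pt_to_nwt(pt: float) -> tuple[float, int]:
    """(1/p_t, floor(1/p_t)): the real and displayed number-willing-to-test."""
    if not (0.0 < pt < 1.0):
        raise ValueError("p_t must lie strictly in (0, 1)")
    nwt = 1.0 / pt
    # guard against float noise at exact reciprocals (1/0.025 -> 40)
    return nwt, int(math.floor(nwt + 1e-9))


@dataclass(frozen=True)
class PreferencePoint:
    """One point on the conservatism/tolerance axis, in its three
    equivalent representations."""

    pt: float
    ratio: tuple[float, float]
    nwt: float
    nwt_display: int

    @classmethod
    def from_pt(cls, pt: float) -> "PreferencePoint":
        nwt, disp = pt_to_nwt(pt)
        return cls(pt=pt, ratio=(pt, 1.0 - pt), nwt=nwt, nwt_display=disp)

    @classmethod
    def from_ratio(cls, a: float, b: float) -> "PreferencePoint":
        pt = ratio_to_pt(a, b)
        nwt, disp = pt_to_nwt(pt)
        return cls(pt=pt, ratio=(a, b), nwt=nwt, nwt_display=disp)


def net_benefit(true_pos: float, false_pos: float, n: float, pt: float) -> float:
    """Net benefit of a strategy producing ``true_pos``/``false_pos`` scans
    among ``n`` patients at threshold probability ``pt``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 < pt < 1.0):
        raise ValueError("p_t must lie strictly in (0, 1)")
    if true_pos < 0 or false_pos < 0 or true_pos + false_pos > n:
        raise ValueError("invalid counts")
    return true_pos / n - (false_pos / n) * pt / (1.0 - pt)


@dataclass
class NetBenefitCurve:
    """Net benefit over a p_t grid, pooled across imputed datasets, with
    the scanned / true-positive / false-positive fractions behind it."""

    strategy_name: str
    grid: np.ndarray
    nb: np.ndarray
    scanned_frac: np.ndarray
    tp_frac: np.ndarray
    fp_frac: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        nwt = np.array([pt_to_nwt(p)[0] for p in self.grid])
        disp = np.array([pt_to_nwt(p)[1] for p in self.grid])
        return pd.DataFrame(
            {
                "strategy": self.strategy_name,
                "pt": self.grid,
                "ratio_a": np.round(self.grid * 100, 6),
                "ratio_b": np.round((1 - self.grid) * 100, 6),
                "nwt": nwt,
                "nwt_display": disp,
                "nb": self.nb,
                "scanned_frac": self.scanned_frac,
                "tp_frac": self.tp_frac,
                "fp_frac": self.fp_frac,
            }
        )


def _odds(grid: np.ndarray) -> np.ndarray:
    return grid / (1.0 - grid)


def _outcome(ds: pd.DataFrame) -> np.ndarray:
    return (ds["scan_result"] == "positive").to_numpy()


def fixed_strategy_curve(
    name: str,
    predicate: Callable[[pd.DataFrame], np.ndarray],
    imputed_set: ImputedCohortSet,
    grid: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Straight-line curve of a fixed scan/no-scan rule: the classification
    does not depend on p_t, only the false-positive weighting does."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    tp, fp, sc = [], [], []
    n = len(imputed_set.source)
    for ds in imputed_set.datasets:
        mask = np.asarray(predicate(ds), dtype=bool)
        y = _outcome(ds)
        tp.append(float((mask & y).sum()))
        fp.append(float((mask & ~y).sum()))
        sc.append(float(mask.sum()))
    tp_f = float(np.mean(tp)) / n
    fp_f = float(np.mean(fp)) / n
    sc_f = float(np.mean(sc)) / n
    nb = tp_f - fp_f * _odds(grid)
    return NetBenefitCurve(
        strategy_name=name,
        grid=grid,
        nb=nb,
        scanned_frac=np.full_like(grid, sc_f),
        tp_frac=np.full_like(grid, tp_f),
        fp_frac=np.full_like(grid, fp_f),
    )


def continuous_model_curve(
    name: str,
    model: RiskModel,
    imputed_set: ImputedCohortSet,
    grid: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Decision curve of a continuous model: at each grid point, scan
    every patient whose predicted risk is at least p_t."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if not model.has_risk_form():
        raise FormUnavailableError(
            f"model {model.name!r} has no probability form for a decision curve"
        )
    n = len(imputed_set.source)
    tp = np.zeros(len(grid))
    fp = np.zeros(len(grid))
    sc = np.zeros(len(grid))
    for ds in imputed_set.datasets:
        risks = model.risks(ds)
        y = _outcome(ds)
        for j, pt in enumerate(grid):
            mask = risks >= pt
            tp[j] += float((mask & y).sum())
            fp[j] += float((mask & ~y).sum())
            sc[j] += float(mask.sum())
    m = imputed_set.m
    tp_f, fp_f, sc_f = tp / (m * n), fp / (m * n), sc / (m * n)
    nb = tp_f - fp_f * _odds(grid)
    return NetBenefitCurve(
        strategy_name=name,
        grid=grid,
        nb=nb,
        scanned_frac=sc_f,
        tp_frac=tp_f,
        fp_frac=fp_f,
    )


def scan_all_curve(
    imputed_set: ImputedCohortSet, grid: np.ndarray | None = None
) -> NetBenefitCurve:
    return fixed_strategy_curve(
        "scan-all", lambda ds: np.ones(len(ds), dtype=bool), imputed_set, grid
    )


def scan_none_curve(
    imputed_set: ImputedCohortSet, grid: np.ndarray | None = None
) -> NetBenefitCurve:
    return fixed_strategy_curve(
        "scan-none", lambda ds: np.zeros(len(ds), dtype=bool), imputed_set, grid
    )


def all_strategy_curves(
    registry: ModelRegistry,
    imputed_set: ImputedCohortSet,
    grid: np.ndarray | None = None,
    models: Sequence[str] | None = None,
    include_references: bool = True,
    include_continuous: bool = True,
) -> list[NetBenefitCurve]:
    """Fixed-strategy curves for every registered strategy (of the selected
    models), continuous decision curves where a probability form exists,
    plus the scan-all / scan-none references."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    curves = []
    if include_references:
        curves.append(scan_all_curve(imputed_set, grid))
        curves.append(scan_none_curve(imputed_set, grid))
    for model in registry:
        if models is not None and model.name not in models:
            continue
        for strat, fn in model.strategies.items():
            curves.append(fixed_strategy_curve(strat, fn, imputed_set, grid))
        if include_continuous and model.has_risk_form():
            curves.append(
                continuous_model_curve(
                    f"{model.name}-continuous", model, imputed_set, grid
                )
            )
    return curves


@dataclass
class OptimalStrategyMap:
    """Stepwise map: which strategy has maximal net benefit on each
    contiguous p_t segment (ties broken toward the strategy scanning
    fewer patients, then alphabetically)."""

    segments: list[tuple[float, float, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lo, hi, name in self.segments:
            rows.append(
                {
                    "pt_low": lo,
                    "pt_high": hi,
                    "nwt_high": pt_to_nwt(lo)[1],
                    "nwt_low": pt_to_nwt(hi)[1],
                    "strategy": name,
                }
            )
        return pd.DataFrame(rows)

    def strategy_at(self, pt: float) -> str:
        for lo, hi, name in self.segments:
            if lo <= pt <= hi:
                return name
        raise ValueError(f"p_t {pt} outside mapped grid")


def optimal_strategy_map(
    curves: Sequence[NetBenefitCurve], tol: float = 1e-12
) -> OptimalStrategyMap:
    """Argmax of net benefit per grid point, merged into segments."""
    if len(curves) == 0:
        raise ValueError("empty curve list")
    grid = curves[0].grid
    for c in curves[1:]:
        if len(c.grid) != len(grid) or not np.allclose(c.grid, grid):
            raise ValueError("curves must share one grid")
    winners = []
    for j in range(len(grid)):
        best_nb = max(c.nb[j] for c in curves)
        cands = [c for c in curves if c.nb[j] >= best_nb - tol]
        cands.sort(key=lambda c: (c.scanned_frac[j], c.strategy_name))
        winners.append(cands[0].strategy_name)
    segments = []
    start = 0
    for j in range(1, len(grid) + 1):
        if j == len(grid) or winners[j] != winners[start]:
            segments.append((float(grid[start]), float(grid[j - 1]), winners[start]))
            start = j
    return OptimalStrategyMap(segments=segments)


def recommended_vs_best_table(
    registry: ModelRegistry,
    imputed_set: ImputedCohortSet,
    grid: np.ndarray | None = None,
    models: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per model and grid point: net benefit of the source-recommended
    strategy vs the best strategy available *within* that model.

    For categorical/guideline models the in-model candidates are their
    registered strategies; for models with a probability form the
    candidates additionally include every risk threshold on the grid.  A
    nonzero discrepancy flags a recommended threshold that is not
    net-benefit-optimal at that preference.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rows = []
    for model in registry:
        if models is not None and model.name not in models:
            continue
        if model.recommended is None:
            continue
        candidates = {
            strat: fixed_strategy_curve(strat, fn, imputed_set, grid)
            for strat, fn in model.strategies.items()
        }
        if model.has_risk_form():
            for thr in grid:
                label = f"{model.name}-risk>={thr:g}"
                candidates[label] = fixed_strategy_curve(
                    label,
                    lambda ds, t=thr: model.risks(ds) >= t,
                    imputed_set,
                    grid,
                )
        rec = candidates[model.recommended]
        names = list(candidates)
        nb_matrix = np.vstack([candidates[k].nb for k in names])
        best_idx = np.argmax(nb_matrix, axis=0)
        for j, pt in enumerate(grid):
            nb_best = float(nb_matrix[best_idx[j], j])
            nb_rec = float(rec.nb[j])
            rows.append(
                {
                    "model": model.name,
                    "pt": float(pt),
                    "nb_recommended": nb_rec,
                    "nb_best": nb_best,
                    "best_strategy": names[best_idx[j]],
                    "discrepancy": nb_best - nb_rec,
                    "flag": bool(nb_best - nb_rec > 1e-9),
                }
            )
    return pd.DataFrame(rows)
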