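"""Net benefit, preference-ratio/NWT conversions, decision curves,
and the optimal-strategy map."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import bonedca as b
from bonedca.dca import NetBenefitCurve

from conftest import random_records


def _imputed_from(df, m=1):
    """Wrap a complete cohort as a trivial imputed set."""
    return b.ImputedCohortSet(
        m=m, iterations=0, seed=0, datasets=[df.copy() for _ in range(m)], source=df
    )


def _cohort_with_risks(rng, n, risks):
    df = random_records(rng, n)
    y = rng.random(n) < risks
    df["scan_result"] = np.where(y, "positive", "negative")
    df["scan_offset_days"] = 10.0
    return df


class TestPreferenceConversions:
    @pytest.mark.parametrize(
        "a,bb,pt", [(1, 99, 0.01), (1, 1, 0.5), (7, 93, 0.07), (1, 39, 0.025)]
    )
    def test_ratio_to_pt(self, a, bb, pt):
        assert b.ratio_to_pt(a, bb) == pytest.approx(pt)

    @pytest.mark.parametrize(
        "pt,nwt_real,nwt_disp",
        [(0.01, 100.0, 100), (0.025, 40.0, 40), (0.03, 100 / 3, 33),
         (0.07, 100 / 7, 14), (0.1, 10.0, 10)],
    )
    def test_pt_to_nwt(self, pt, nwt_real, nwt_disp):
        real, disp = b.pt_to_nwt(pt)
        assert real == pytest.approx(nwt_real)
        assert disp == nwt_disp

    def test_preference_point_representations_consistent(self):
        p = b.PreferencePoint.from_ratio(3, 97)
        assert p.pt == pytest.approx(0.03)
        assert p.nwt == pytest.approx(1 / p.pt)
        assert p.nwt_display == 33

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_pt_rejected(self, bad):
        with pytest.raises(ValueError):
            b.pt_to_nwt(bad)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            b.ratio_to_pt(0, 5)


class TestNetBenefit:
    def test_scan_none_is_zero(self):
        assert b.net_benefit(0, 0, 100, 0.05) == 0.0

    def test_perfect_strategy_attains_prevalence(self):
        for pt in (0.01, 0.05, 0.099):
            assert b.net_benefit(13, 0, 100, pt) == pytest.approx(0.13)

    def test_scan_all_at_published_prevalence(self):
        # prevalence 8.7%, pt 0.025: 0.087 - 0.913 * 0.025/0.975
        nb = b.net_benefit(87, 913, 1000, 0.025)
        assert nb == pytest.approx(0.087 - 0.913 * 0.025 / 0.975)
        assert nb == pytest.approx(0.0636, abs=5e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            b.net_benefit(1, 1, 0, 0.05)
        with pytest.raises(ValueError):
            b.net_benefit(60, 60, 100, 0.05)


class TestCurves:
    def test_scan_none_curve_identically_zero(self, imputed):
        curve = b.scan_none_curve(imputed)
        assert np.all(curve.nb == 0.0)

    def test_everybody_strategy_equals_scan_all_reference(self, imputed):
        ref = b.scan_all_curve(imputed)
        allscan = b.fixed_strategy_curve(
            "everyone", lambda ds: np.ones(len(ds), dtype=bool), imputed
        )
        np.testing.assert_allclose(allscan.nb, ref.nb)

    def test_net_benefit_bounded_by_prevalence(self, imputed, registry):
        prev = np.mean(
            [
                (ds.scan_result == "positive").mean()
                for ds in imputed.datasets
            ]
        )
        for curve in b.all_strategy_curves(registry, imputed):
            assert np.all(curve.nb <= prev + 1e-12), curve.strategy_name

    def test_fixed_strategy_nb_strictly_decreasing_when_fp_positive(self, imputed):
        curve = b.scan_all_curve(imputed)
        assert curve.fp_frac[0] > 0
        assert np.all(np.diff(curve.nb) < 0)

    def test_scan_all_crosses_zero_at_prevalence_odds(self):
        rng = np.random.default_rng(7)
        df = _cohort_with_risks(rng, 4000, np.full(4000, 0.05))
        imputed = _imputed_from(df)
        prev = (df.scan_result == "positive").mean()
        grid = b.default_grid(0.01, 0.10, 0.001)
        curve = b.scan_all_curve(imputed, grid)
        # nb(pt) = prev - (1-prev) pt/(1-pt) changes sign exactly at pt = prev
        signs = np.sign(curve.nb)
        crossing = grid[np.flatnonzero(np.diff(signs) < 0)[0]]
        assert abs(crossing - prev) <= 0.001 + 1e-9

    def test_curve_values_equal_naive_per_patient_recount(self, registry):
        rng = np.random.default_rng(8)
        df = _cohort_with_risks(rng, 200, np.full(200, 0.15))
        imputed = _imputed_from(df)
        grid = b.default_grid()
        y = (df.scan_result == "positive").to_numpy()
        for strat, _, fn in registry.strategies():
            curve = b.fixed_strategy_curve(strat, fn, imputed, grid)
            mask = np.asarray(fn(df), dtype=bool)
            for j, pt in enumerate(grid[:: 30]):
                tp = int((mask & y).sum())
                fp = int((mask & ~y).sum())
                expected = tp / 200 - (fp / 200) * pt / (1 - pt)
                assert curve.nb[grid.tolist().index(pt)] == pytest.approx(expected)

    def test_dominance_when_fewer_false_positives_same_true_positives(self):
        rng = np.random.default_rng(9)
        df = _cohort_with_risks(rng, 500, np.full(500, 0.2))
        y = (df.scan_result == "positive").to_numpy()
        imputed = _imputed_from(df)
        neg_idx = np.flatnonzero(~y)
        mask_b = y.copy()
        mask_b[neg_idx[:100]] = True  # same TP, 100 extra FP
        a = b.fixed_strategy_curve("a", lambda ds: y, imputed)
        bb = b.fixed_strategy_curve("b", lambda ds: mask_b, imputed)
        assert np.all(a.nb > bb.nb)


class TestContinuousCurves:
    def _calibrated_setup(self, n=30_000, seed=10):
        rng = np.random.default_rng(seed)
        risks = expit(rng.normal(-3.0, 1.3, n))
        df = _cohort_with_risks(rng, n, risks)
        model = b.RiskModel(
            name="oracle", kind="continuous",
            score=lambda d: risks[: len(d)], risk=lambda d: risks[: len(d)],
        )
        return df, model, risks

    def test_calibrated_model_weakly_dominates_its_fixed_thresholds(self):
        df, model, risks = self._calibrated_setup()
        imputed = _imputed_from(df)
        grid = b.default_grid(0.01, 0.10, 0.01)
        cont = b.continuous_model_curve("cont", model, imputed, grid)
        mc_slack = 3 * np.sqrt(0.1 / len(df))
        for thr in (0.02, 0.05, 0.08):
            fixed = b.fixed_strategy_curve(
                f"thr{thr}", lambda ds, t=thr: risks[: len(ds)] >= t, imputed, grid
            )
            assert np.all(cont.nb >= fixed.nb - mc_slack)

    def test_predictions_below_grid_reduce_to_scan_none(self):
        rng = np.random.default_rng(11)
        df = _cohort_with_risks(rng, 300, np.full(300, 0.05))
        model = b.RiskModel(
            name="tiny", kind="continuous",
            score=lambda d: np.full(len(d), 0.001),
            risk=lambda d: np.full(len(d), 0.001),
        )
        curve = b.continuous_model_curve("tiny", model, _imputed_from(df), b.default_grid())
        assert np.all(curve.nb == 0.0)

    def test_miscalibrated_model_beaten_by_fixed_strategy_at_some_pt(self):
        """Odds-deflated predictions make the threshold-at-pt rule scan too
        few patients; the model's own recommended fixed cut-off then wins
        somewhere on the grid."""
        rng = np.random.default_rng(12)
        n = 20_000
        true = expit(rng.normal(-3.0, 1.3, n))
        reported = expit(logit(true) + np.log(0.25))  # 4x under-estimated odds
        df = _cohort_with_risks(rng, n, true)
        model = b.RiskModel(
            name="shrunk", kind="continuous",
            score=lambda d: reported[: len(d)], risk=lambda d: reported[: len(d)],
        )
        imputed = _imputed_from(df)
        grid = b.default_grid()
        cont = b.continuous_model_curve("shrunk-cont", model, imputed, grid)
        fixed = b.fixed_strategy_curve(
            "shrunk-rec", lambda ds: reported[: len(ds)] >= 0.0125, imputed, grid
        )
        assert np.any(fixed.nb > cont.nb + 1e-4)

    def test_no_probability_form_is_an_error(self, registry, imputed):
        with pytest.raises(b.FormUnavailableError):
            b.continuous_model_curve("x", registry["chybowski"], imputed)


class TestOptimalMap:
    def _line(self, name, grid, nb, scanned=0.5):
        return NetBenefitCurve(
            strategy_name=name, grid=grid, nb=np.asarray(nb, float),
            scanned_frac=np.full(len(grid), scanned),
            tp_frac=np.zeros(len(grid)), fp_frac=np.zeros(len(grid)),
        )

    def test_single_curve_one_segment(self):
        grid = b.default_grid(0.01, 0.05, 0.01)
        omap = b.optimal_strategy_map([self._line("only", grid, np.ones(5))])
        assert omap.segments == [(0.01, 0.05, "only")]

    def test_two_crossing_curves_give_two_segments(self):
        grid = np.array([0.01, 0.02, 0.03, 0.04])
        c1 = self._line("falling", grid, [1.0, 0.6, 0.2, 0.0])
        c2 = self._line("flat", grid, [0.4, 0.4, 0.4, 0.4])
        omap = b.optimal_strategy_map([c1, c2])
        assert omap.segments == [(0.01, 0.02, "falling"), (0.03, 0.04, "flat")]
        assert omap.strategy_at(0.035) == "flat"

    def test_tie_broken_toward_fewer_scans(self):
        grid = np.array([0.01])
        greedy = self._line("greedy", grid, [0.3], scanned=0.9)
        frugal = self._line("frugal", grid, [0.3], scanned=0.2)
        omap = b.optimal_strategy_map([greedy, frugal])
        assert omap.segments[0][2] == "frugal"

    def test_empty_curve_list_rejected(self):
        with pytest.raises(ValueError):
            b.optimal_strategy_map([])

    def test_scan_all_wins_at_conservative_end_on_risk_concentrated_cohort(
        self, imputed, registry
    ):
        curves = b.all_strategy_curves(registry, imputed)
        omap = b.optimal_strategy_map(curves)
        assert omap.segments[0][2] == "scan-all"
        assert omap.segments[-1][2] != "scan-all"


class TestRecommendedVsBest:
    def test_single_strategy_categorical_model_has_zero_discrepancy_where_scanning_helps(
        self, imputed, registry
    ):
        table = b.recommended_vs_best_table(
            registry, imputed, models=["osullivan"]
        )
        # the only in-model strategy is the recommended one, so any
        # discrepancy can only come from scan-none-like degenerate rules
        assert (table.nb_best >= table.nb_recommended - 1e-12).all()
        helped = table[table.nb_recommended > 0]
        assert (helped.discrepancy.abs() < 1e-12).all()

    def test_miscalibrated_continuous_model_flags_discrepancy(self):
        rng = np.random.default_rng(13)
        n = 10_000
        true = expit(rng.normal(-3.0, 1.3, n))
        reported = expit(logit(true) + np.log(0.25))
        df = _cohort_with_risks(rng, n, true)
        reg = b.ModelRegistry()
        reg.register(
            b.RiskModel(
                name="shrunk", kind="continuous",
                score=lambda d: reported[: len(d)],
                risk=lambda d: reported[: len(d)],
                strategies={"shrunk-rec": lambda d: reported[: len(d)] >= 0.0125},
                recommended="shrunk-rec",
            )
        )
        table = b.recommended_vs_best_table(reg, _imputed_from(df))
        assert table.flag.any()
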