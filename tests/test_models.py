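"""Staging-model rules: published thresholds, score arithmetic, strategy
nesting and monotonicity, and registry behaviour."""
import numpy as np
import pandas as pd
import pytest

import bonedca as b
from bonedca import models as M

from conftest import make_record, random_records


class TestWangScore:
    def test_all_indicators_zero_reduces_to_constant_terms(self):
        # PSA -> 0+ makes the log term vanish; T1c and GS 3+3 zero the
        # indicators, leaving -6.40 + 2.169
        d = M.wang_score(1e-12, "T1c", 3, 3)
        assert d == pytest.approx(-4.231, abs=1e-6)

    def test_printed_coefficients_at_high_risk_profile(self):
        d = M.wang_score(20.0, "T4", 4, 3)
        expected = -6.40 + 2.39 + 0.87 * np.log(21.0) + 0.93 + 2.169
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(1.738, abs=1e-3)

    def test_strictly_increasing_in_psa(self):
        assert M.wang_score(10.01, "T1c", 3, 3) > M.wang_score(9.99, "T1c", 3, 3)

    def test_probability_is_inverse_logit_of_score(self):
        # engineer a record whose linear predictor is exactly zero
        psa = float(np.exp(4.231 / 0.87) - 1.0)
        assert M.wang_score(psa, "T1c", 3, 3) == pytest.approx(0.0, abs=1e-9)
        assert M.wang_probability(psa, "T1c", 3, 3) == pytest.approx(0.5, abs=1e-9)

    def test_scan_direction_as_printed_and_inverted(self):
        low = make_record(psa_ng_ml=1.0)  # D < 0
        high = make_record(psa_ng_ml=500.0, t_stage="T4", gleason_secondary=4.0)
        assert M.classify_wang(low) and not M.classify_wang(high)
        assert not M.classify_wang(low, invert=True)
        assert M.classify_wang(high, invert=True)


RULE_CASES = [
    # EAU 2020: PSA > 20, T >= T2c, or GS >= 4+3
    (M.classify_eau, dict(psa_ng_ml=25.0), True),
    (M.classify_eau, dict(psa_ng_ml=5.0, gleason_secondary=4.0), False),
    (M.classify_eau, dict(psa_ng_ml=5.0, gleason_primary=4.0, gleason_secondary=3.0), True),
    (M.classify_eau, dict(t_stage="T2c"), True),
    (M.classify_eau, dict(t_stage="T2b"), False),
    # EAU high-risk only: PSA > 20, GS >= 8, or T >= T3
    (M.classify_eau_high_risk, dict(psa_ng_ml=25.0), True),
    (
        M.classify_eau_high_risk,
        dict(psa_ng_ml=8.0, gleason_primary=4.0, gleason_secondary=3.0, t_stage="T2a"),
        False,
    ),
    (M.classify_eau_high_risk, dict(gleason_primary=4.0, gleason_secondary=4.0), True),
    (M.classify_eau_high_risk, dict(t_stage="T3a"), True),
    # AUA 2018
    (M.classify_aua, dict(psa_ng_ml=12.0, gleason_secondary=4.0), True),
    (M.classify_aua, dict(psa_ng_ml=12.0), False),
    (M.classify_aua, dict(t_stage="T2b"), True),
    (M.classify_aua, dict(psa_ng_ml=21.0), True),
    # NCCN 2019
    (M.classify_nccn, dict(gleason_secondary=4.0, pct_pos_cores=60.0, psa_ng_ml=8.0), True),
    (M.classify_nccn, dict(gleason_secondary=4.0, pct_pos_cores=40.0, psa_ng_ml=8.0), False),
    (M.classify_nccn, dict(psa_ng_ml=21.0, pct_pos_cores=0.0), True),
    (M.classify_nccn, dict(t_stage="T3a", pct_pos_cores=0.0), True),
    # O'Sullivan
    (M.classify_osullivan, dict(t_stage="T4"), True),
    (M.classify_osullivan, dict(psa_ng_ml=21.0), True),
    (
        M.classify_osullivan,
        dict(psa_ng_ml=5.0, t_stage="T2a", gleason_secondary=4.0),
        False,
    ),
    # Briganti
    (M.classify_briganti, dict(gleason_primary=4.0, gleason_secondary=4.0), True),
    (M.classify_briganti, dict(psa_ng_ml=12.0, t_stage="T2a"), True),
    (M.classify_briganti, dict(psa_ng_ml=12.0, t_stage="T1c"), False),
    # Ho
    (M.classify_ho, dict(psa_ng_ml=5.0, n_stage_positive=1.0), True),
    (M.classify_ho, dict(psa_ng_ml=10.5), True),
    (M.classify_ho, dict(psa_ng_ml=5.0), False),
]


@pytest.mark.parametrize("rule,overrides,expected", RULE_CASES)
def test_published_rule_thresholds(rule, overrides, expected):
    assert bool(rule(make_record(**overrides))) is expected


class TestPsaThresholds:
    def test_strict_inequality_at_the_threshold(self):
        assert M.classify_simple_psa(make_record(psa_ng_ml=10.1), 10.0)
        assert not M.classify_simple_psa(make_record(psa_ng_ml=10.0), 10.0)


class TestGroupings:
    @pytest.mark.parametrize(
        "overrides,group",
        [
            (dict(gleason_primary=4.0, gleason_secondary=3.0, psa_ng_ml=5.0), 3),
            (dict(gleason_primary=4.0, gleason_secondary=4.0, psa_ng_ml=5.0), 4),
            (dict(psa_ng_ml=4.0), 1),
            (dict(gleason_primary=4.0, gleason_secondary=5.0), 5),
            (dict(t_stage="T4"), 5),
            (dict(psa_ng_ml=25.0, t_stage="T3a"), 5),
            (dict(psa_ng_ml=15.0), 2),
            (dict(gleason_secondary=4.0, psa_ng_ml=15.0), 3),
        ],
    )
    def test_cambridge_five_tier_grouping(self, overrides, group):
        assert M.gnanapragasam_group(make_record(**overrides)) == group

    @pytest.mark.parametrize(
        "primary,secondary,gg,scans",
        [(3, 3, 1, False), (3, 4, 2, False), (4, 3, 3, True), (4, 4, 4, True),
         (5, 5, 5, True), (3, 5, 4, True)],
    )
    def test_isup_grade_groups_and_strategy(self, primary, secondary, gg, scans):
        rec = make_record(gleason_primary=float(primary), gleason_secondary=float(secondary))
        assert M.isup_grade_group(rec) == gg
        assert bool(M.classify_isup(rec)) is scans

    def test_lai_psa_categories_are_ordered(self):
        psas = [5.0, 15.0, 30.0, 80.0]
        groups = [M.lai_psa_group(make_record(psa_ng_ml=p)) for p in psas]
        assert groups == [0, 1, 2, 3]


class TestStrategyProperties:
    def test_eau_high_risk_scans_subset_of_eau(self):
        df = random_records(np.random.default_rng(0), 400)
        high = np.atleast_1d(M.classify_eau_high_risk(df))
        full = np.atleast_1d(M.classify_eau(df))
        assert not np.any(high & ~full)

    def test_cambridge_group_strategies_nest(self):
        df = random_records(np.random.default_rng(1), 400)
        g3 = np.atleast_1d(M.classify_gnanapragasam(df, 3))
        g4 = np.atleast_1d(M.classify_gnanapragasam(df, 4))
        g5 = np.atleast_1d(M.classify_gnanapragasam(df, 5))
        assert not np.any(g5 & ~g4) and not np.any(g4 & ~g3)

    def test_raising_psa_never_cancels_a_scan(self, registry):
        df = random_records(np.random.default_rng(2), 200)
        raised = df.assign(psa_ng_ml=df.psa_ng_ml * 3 + 5)
        for strat, model_name, fn in registry.strategies():
            if strat == "wang-d":
                continue  # printed direction is risk-decreasing by design
            before = np.atleast_1d(fn(df))
            after = np.atleast_1d(fn(raised))
            assert not np.any(before & ~after), strat

    def test_strategies_deterministic_and_total_on_complete_records(self, registry):
        df = random_records(np.random.default_rng(3), 100)
        for strat, _, fn in registry.strategies():
            r1 = np.atleast_1d(fn(df))
            r2 = np.atleast_1d(fn(df))
            assert r1.dtype == bool and len(r1) == len(df)
            assert np.array_equal(r1, r2)

    def test_missing_predictor_raises(self):
        rec = make_record(psa_ng_ml=np.nan)
        for rule in (M.classify_eau, M.classify_aua, M.classify_nccn, M.classify_ho):
            with pytest.raises(M.MissingPredictorError):
                rule(rec)


class TestRegistry:
    def test_eleven_models_with_unique_strategy_names(self, registry):
        assert len(registry.names()) == 11
        strats = [s for s, _, _ in registry.strategies()]
        assert len(strats) == len(set(strats))

    def test_duplicate_registration_rejected(self, registry):
        with pytest.raises(ValueError):
            registry.register(registry["wang"])

    def test_wang_probability_form_registered_by_default(self, registry):
        rec = make_record(
            psa_ng_ml=20.0, t_stage="T4", gleason_primary=4.0, gleason_secondary=3.0
        )
        p = registry.predict_continuous("wang", rec)
        assert 0.8 < p < 0.9  # expit(1.738)

    def test_unregistered_probability_form_is_an_explicit_error(self, registry):
        with pytest.raises(M.FormUnavailableError):
            registry.predict_continuous("chybowski", make_record())
        with pytest.raises(M.FormUnavailableError):
            registry.predict_continuous("eau", make_record())

    def test_user_supplied_chybowski_lookup_passthrough(self):
        reg = b.default_registry(
            chybowski_curve=[[5.0, 0.05], [10.0, 0.10], [20.0, 0.30]]
        )
        p = reg.predict_continuous("chybowski", make_record(psa_ng_ml=10.0))
        assert p == pytest.approx(0.10)

    def test_group_risk_passthrough_and_validation(self):
        reg = b.default_registry(group_risks={"lai": {2: 0.29}})
        assert reg["lai"].group_predicted_risk(2) == pytest.approx(0.29)
        bad = b.default_registry(group_risks={"lai": {2: 1.2}})
        with pytest.raises(ValueError):
            bad["lai"].group_predicted_risk(2)

    def test_guideline_models_report_no_numeric_risk(self, registry):
        df = random_records(np.random.default_rng(4), 10)
        with pytest.raises(M.NoNumericRiskError):
            registry["eau"].risks(df)

    def test_single_record_prediction_object(self, registry):
        pred = registry["gnanapragasam"].predict(
            make_record(gleason_primary=4.0, gleason_secondary=4.0)
        )
        assert pred.kind == "categorical" and pred.risk_group == 4
        pred2 = registry["wang"].predict(make_record())
        assert pred2.kind == "continuous" and 0 < pred2.risk_probability < 1
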