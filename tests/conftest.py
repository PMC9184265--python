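import dataclasses

import numpy as np
import pandas as pd
import pytest

import bonedca as b


def make_record(**overrides):
    """A complete patient record; override any field."""
    rec = {
        "patient_id": "X0",
        "age_years": 65.0,
        "psa_ng_ml": 5.0,
        "gleason_primary": 3.0,
        "gleason_secondary": 3.0,
        "pct_pos_cores": 20.0,
        "t_stage": "T1c",
        "n_stage_positive": 0.0,
        "scan_result": "none",
        "scan_offset_days": np.nan,
        "treatment_setting": "public",
        "survival_months": 24.0,
        "dead": False,
        "year_of_diagnosis": 2010,
    }
    rec.update(overrides)
    return rec


def random_records(rng, n):
    """Random complete records spanning the predictor space."""
    patterns = [(3, 3), (3, 4), (4, 3), (4, 4), (4, 5), (5, 4), (5, 5)]
    pk = rng.integers(0, len(patterns), n)
    return pd.DataFrame(
        [
            make_record(
                patient_id=f"R{i}",
                psa_ng_ml=float(np.round(rng.lognormal(2.2, 1.0), 2)) + 0.01,
                gleason_primary=float(patterns[pk[i]][0]),
                gleason_secondary=float(patterns[pk[i]][1]),
                pct_pos_cores=float(np.round(rng.uniform(0, 100), 1)),
                t_stage=b.T_STAGES[rng.integers(0, 10)],
                n_stage_positive=float(rng.integers(0, 2)),
            )
            for i in range(n)
        ]
    )


@pytest.fixture(scope="session")
def registry():
    return b.default_registry()


@pytest.fixture(scope="session")
def bundle():
    return b.generate_cohort(b.GeneratorConfig(n_patients=1200, seed=11))


@pytest.fixture(scope="session")
def prepared_cohort(bundle):
    cohort = b.flag_staging_scans(bundle.cohort, window_days=140)
    indet = set(cohort.loc[cohort.scan_result == "indeterminate", "patient_id"])
    labels = {k: v for k, v in bundle.followup_labels.items() if k in indet}
    return b.reclassify_indeterminate(cohort, labels)


@pytest.fixture(scope="session")
def imputed(prepared_cohort):
    return b.mice_impute(prepared_cohort, m=3, iterations=5, seed=21)


@pytest.fixture(scope="session")
def complete_config():
    """Generator settings producing a cohort with no missing cells."""
    cfg = b.GeneratorConfig(n_patients=400, seed=5)
    cfg = dataclasses.replace(
        cfg,
        missingness={
            k: {**v, "rate": 0.0} for k, v in cfg.missingness.items()
        },
        scan_probs={
            s: {"public": 1.0, "private": 1.0} for s in cfg.scan_probs
        },
        indeterminate_rate=0.0,
        late_scan_frac=0.0,
    )
    return cfg
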