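"""Generate a synthetic staging registry and inspect its structure.

The generator emulates a population-based prostate-cancer registry: PSA,
Gleason pattern, T-stage and biopsy-core marginals; a latent logistic model
for bone-scan positivity calibrated so ~8.7% of scanned patients are
positive; and missing-at-random masking tied to treatment setting and risk
stratum.  A parallel truth table retains every pre-masking value.
"""
import bonedca as b

bundle = b.generate_cohort(b.GeneratorConfig(n_patients=5000, seed=1))
cohort, truth = bundle.cohort, bundle.truth

scanned = cohort.scan_result.isin(["positive", "negative"])
print(f"patients:                 {len(cohort)}")
print(f"with staging scan result: {scanned.sum()} ({scanned.mean():.1%})")
print(f"positivity among scanned: "
      f"{(cohort.scan_result[scanned] == 'positive').mean():.1%}")
print(f"indeterminate scans:      {(cohort.scan_result == 'indeterminate').sum()}")
print("missingness by variable:")
for var in ("psa_ng_ml", "t_stage", "gleason_primary", "pct_pos_cores",
            "n_stage_positive"):
    print(f"  {var:<18s} {cohort[var].isna().mean():6.1%}")
print(f"true positivity (all patients, from truth table): "
      f"{truth.true_scan_positive.mean():.1%}")
# The gap between observed positivity among scanned and the cohort-wide true
# rate is the selective-scanning mechanism the imputation must undo.
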