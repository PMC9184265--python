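"""Net-benefit comparison of staging strategies across preferences.

Net benefit weighs detected positive scans against scans performed, at a
threshold probability p_t (equivalently a preference ratio or a
number-willing-to-test NWT = 1/p_t).  Fixed strategies are straight lines;
the optimal-strategy map shows which rule wins on each preference segment.
"""
import bonedca as b

bundle = b.generate_cohort(b.GeneratorConfig(n_patients=3000, seed=6))
cohort = b.flag_staging_scans(bundle.cohort)
indet = set(cohort.loc[cohort.scan_result == "indeterminate", "patient_id"])
cohort = b.reclassify_indeterminate(
    cohort, {k: v for k, v in bundle.followup_labels.items() if k in indet}
)
imputed = b.mice_impute(cohort, m=5, iterations=10, seed=7)
registry = b.default_registry()

grid = b.default_grid(0.01, 0.10, 0.001)  # preference ratios 1:99 .. 1:9
curves = b.all_strategy_curves(registry, imputed, grid)

point = b.PreferencePoint.from_ratio(1, 39)
print(f"preference 1:39 = p_t {point.pt:.3f} = NWT {point.nwt_display}")
j = list(grid).index(point.pt)
print("net benefit at NWT 40 (top five strategies):")
for c in sorted(curves, key=lambda c: -c.nb[j])[:5]:
    print(f"  {c.strategy_name:<18s} nb={c.nb[j]:.4f} "
          f"scanned={c.scanned_frac[j]:.1%}")

omap = b.optimal_strategy_map(curves)
print("\noptimal strategy by preference segment:")
for lo, hi, name in omap.segments:
    print(f"  p_t {lo:.3f}-{hi:.3f} "
          f"(NWT {b.pt_to_nwt(hi)[1]}-{b.pt_to_nwt(lo)[1]}): {name}")
# Typical pattern: scan-all wins at conservative preferences (high NWT),
# guideline rules in the middle, and narrow high-risk-only strategies at
# the tolerant end — net benefit, not AUC, picks the winner per segment.
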