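"""One-call pipeline: synthesise, window, impute, validate, compare.

Writes every output table (cohort summary, validation metrics, decision
curves, optimal map, recommended-vs-best) as delimited text; the run is
byte-reproducible under its master seed.
"""
import bonedca as b

config = b.RunConfig(
    generator=b.GeneratorConfig(n_patients=2000),
    seed=42, m=5, iterations=10, out_dir="scratch/demo-run",
)
result = b.run_pipeline(config)

print(f"outputs in {result.out_dir}:")
for p in sorted(result.out_dir.iterdir()):
    print(f"  {p.name}")

pos = result.cohort_summary.query("variable == 'scan_positivity'").overall.iloc[0]
print(f"\nscan positivity among scanned: {pos}%")
aucs = result.validation.query("metric == 'auc'").dropna(subset=["estimate"])
best = aucs.loc[aucs.estimate.idxmax()]
print(f"best-discriminating model: {best.model} "
      f"(AUC {best.estimate:.2f} [{best.ci_low:.2f}, {best.ci_high:.2f}])")
print("optimal strategy per preference segment:")
for _, row in result.optimal_map.iterrows():
    print(f"  p_t {row.pt_low:.3f}-{row.pt_high:.3f}: {row.strategy}")
disc = result.recommended_vs_best.query("flag")
print(f"\npreference points where a model's recommended strategy is "
      f"not its in-model optimum: {len(disc)} of {len(result.recommended_vs_best)}")
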