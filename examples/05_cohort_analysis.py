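"""End-to-end validation study on a 10-case synthetic cohort.

Runs phantom -> biopsy -> registration -> contouring -> scoring -> statistics
and prints the per-method summary (mean +/- SD of DSC, Youden index,
sensitivity, specificity), the selected best threshold, the Kruskal-Wallis
comparison across methods and the volume-factor correlations.
"""

from iplconcord import CohortSpec, run_cohort

result = run_cohort(CohortSpec(n_patients=10, seed=1))

print("per-method summary (mean +/- SD across lesions):")
for _, row in result.summary.iterrows():
    print(f"  {row['method']:>10}: DSC {row['dsc_mean']:.2f}+/-{row['dsc_sd']:.2f}"
          f"  YI {row['yi_mean']:.2f}"
          f"  sens {100 * row['sensitivity_mean']:.0f}%"
          f"  spec {100 * row['specificity_mean']:.0f}%  (n={row['n']})")

print(f"\nbest automatic threshold on this cohort: "
      f"{int(result.best_threshold * 100)}% of SUVmax "
      f"(flags: {result.best_threshold_info})")
kw = result.method_comparison
print(f"Kruskal-Wallis across methods: H={kw.statistic:.2f}, p={kw.p_value:.2g}")

vol = result.factor_correlations.query("factor == 'volume'")
print("\nvolume-threshold indicator correlations with per-lesion DSC:")
for _, row in vol.iterrows():
    r = "nan" if row.isna()["r"] else f"{row['r']:.2f}"
    print(f"  >= {row['stratum']:>5} of gland, {row['method']:>10}: r = {r}")
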