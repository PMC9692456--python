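"""PLS-DA with repeated double cross-validation and variable selection.

The outer CV loop gives an honest accuracy estimate; the inner loop picks
the number of latent variables; coefficient stability across all outer
models decides which markers significantly contribute. A reduced model is
then refit on the selected panel.
"""

from frailmark import (
    DCVConfig,
    SyntheticConfig,
    assess_variable_significance,
    generate_cohort,
    refit_reduced_model,
    run_dcv_classification,
)

table = generate_cohort(SyntheticConfig(), seed=1)
cfg = DCVConfig(repetitions=20, seed=1)

full = run_dcv_classification(table, config=cfg)
print(f"full model: accuracy {100 * full.mean:.1f} ± {100 * full.sd:.1f}% "
      f"(PFS {100 * full.per_rep_class_acc['PFS'].mean():.1f}%, "
      f"CONTROL {100 * full.per_rep_class_acc['CONTROL'].mean():.1f}%), "
      f"mean latent variables {full.mean_complexity():.1f}")

verdicts = assess_variable_significance(full)
selected = [v.name for v in verdicts if v.significant]
for v in verdicts:
    flag = "*" if v.significant else " "
    print(f"  {flag} {v.name:>10}  coef {v.median_coef:+.3f}  ci ({v.ci[0]:+.3f}, {v.ci[1]:+.3f})  {v.direction}")

reduced = refit_reduced_model(table, selected, config=cfg)
print(f"reduced model ({len(selected)} markers): "
      f"accuracy {100 * reduced.mean:.1f} ± {100 * reduced.sd:.1f}%")
mean, lo, hi = reduced.sample_score_summary()
print(f"canonical-variate scores: PFS mean {mean[table.group_mask('PFS')].mean():+.2f}, "
      f"CONTROL mean {mean[table.group_mask('CONTROL')].mean():+.2f}")
print()
print(
    "Accuracies are outer-loop (held-out) estimates, mean ± SD across the "
    "repeated fold reshuffles; starred markers have jackknife-calibrated "
    "coefficient intervals excluding zero. PF&S samples sit at negative "
    "canonical-variate scores by convention."
)
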