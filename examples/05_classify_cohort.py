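"""Full protocol on a small synthetic cohort.

Generates a labeled cohort, extracts the 10 handcrafted features per volume
(3 mixture + 3 Euler-curve FPC scores + 4 texture), tunes a random forest by
10-fold cross-validated AUC on a 70% training split, and evaluates on the
held-out 30%: AUC and specificity at 95% sensitivity with percentile
bootstrap confidence intervals, plus Mean Decrease Gini importance.
"""

from hbpqa import ExperimentConfig, generate_cohort, run_experiment

cohort = generate_cohort(n_adequate=40, n_suboptimal=20, seed=5)
cfg = ExperimentConfig(rf_grid=((2, 250), (3, 250), (6, 250)),
                       cv_folds=5, bootstrap_B=500)
report = run_experiment(cohort, seed=0, cfg=cfg)

print(f"test AUC = {report.auc:.3f}  "
      f"95% CI [{report.auc_ci[0]:.3f}, {report.auc_ci[1]:.3f}]")
print(f"specificity at 95% sensitivity = "
      f"{report.specificity_at_95sens:.3f}  "
      f"95% CI [{report.spec_ci[0]:.3f}, {report.spec_ci[1]:.3f}]")
print("feature importance ranks (1 = most important):")
for feat, rank in sorted(report.mdg_ranks.items(), key=lambda kv: kv[1]):
    print(f"  {rank:2d}. {feat:18s} MDG={report.mdg[feat]:.3f}")
print()
print("With the default clear contrast gap the classes separate almost "
      "perfectly; shrink the gap (generate_cohort's base spec) to watch "
      "AUC fall toward 0.5.")
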