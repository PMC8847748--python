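"""Train the hybrid model on a planted-signal cohort and cross-validate.

A two-arm cohort is generated whose arms differ by 4 ADAS-cog points of
drift per 3-month step — enough signal that conversion is predictable.
Five-fold cross-validation reports held-out discrimination, and the
withdrawal experiment re-scores each fold's model without the 3-month
visit.  Epochs are reduced from the full training schedule to keep the
example fast; expect a couple of minutes.
"""

from cogconv.experiments import planted_signal_cv

result = planted_signal_cv(n=300, seed=7, epochs=200, k=5)

metrics = result["cv"].metrics
for month in (3, 6):
    m = metrics[metrics["month"] == month]
    print(f"{month}-month held-out AUC per fold:",
          [round(a, 3) for a in m["auc"]])
    print(f"  mean accuracy {m['accuracy'].mean():.3f}, "
          f"sensitivity {m['sensitivity'].mean():.3f}, "
          f"specificity {m['specificity'].mean():.3f}")

wd = result["withdrawal"]
print("\nwithdrawal experiment (6-month AUC, per fold):")
print(wd.round(3).to_string(index=False))
print(f"\nmean AUC full {wd['auc_full'].mean():.3f} vs "
      f"withdrawn {wd['auc_withdrawn'].mean():.3f}")
# The drop measures how much 6-month discrimination relies on the 3-month
# visit: with AR(1)-correlated visit noise the mid-point is informative,
# so removing it costs AUC, mirroring the motivating study's finding.
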