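"""The full risk-stratification pipeline, end to end.

Stratified 70/30 derivation/validation split, univariate screen,
bootstrap stability selection within the clinical/echo/lab domains, tree
growth on the derivation cohort, per-subgroup Kaplan-Meier and Cox
reporting on both cohorts, and a temporal-consistency split.

Runs a reduced bootstrap (B=50) to finish in about a minute; the
published analysis used B=500.
"""

import survstrat as ss

cohort = ss.generate_cohort(ss.default_generator_spec(n=1317, seed=11))
config = ss.AnalysisConfig(bootstrap_b=50, seed=11)

report = ss.run_pipeline(cohort, config)

print(f"derivation / validation: {report.split.derivation_ids.size} / "
      f"{report.split.validation_ids.size}")
print(f"covariates retained by stability selection: {report.selection.union}")
print(f"tree: {report.tree.n_leaves} subgroups, "
      f"root split on {report.tree.root.variable}")

cols = ["subgroup", "criteria", "n", "events", "km_1y", "km_6y", "hr"]
print("\nderivation subgroups (HR vs best-surviving subgroup):")
print(report.derivation_table[cols].round(2).to_string(index=False))
print("\nvalidation subgroups (tree frozen, patients re-routed):")
print(report.validation_table[cols].round(2).to_string(index=False))

# The HR ladder rises as 6-year survival falls, and the validation table
# reproduces the derivation ordering with wider intervals (n=394).
# Note the 85% stability threshold is deliberately harsh: on a 923-patient
# derivation cohort only the dominant predictor (albumin) clears it, so
# the pipeline's tree is shallower than one grown on all covariates --
# bootstrap-stepwise inclusion frequencies of weaker true predictors sit
# in the 0.5-0.8 range alongside inflated null frequencies.
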