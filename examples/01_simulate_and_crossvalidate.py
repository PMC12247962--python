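"""Simulate a longitudinal cytometry cohort and cross-validate the model.

Builds a 30-subject, two-timepoint cohort in which class-1 subjects carry a
+1.5 mean shift on markers M0-M2, then runs stratified 5-fold subject-level
cross-validation of the full pipeline (autoencoder -> sparse GP ->
attention -> logistic head).
"""

import cytogpnet as cg
from cytogpnet.experiments import benchmark_train_config

sim = cg.SimConfig(
    n_subjects=30, n_timepoints=2, n_markers=10, n_populations=3,
    informative=(0, 1, 2), effect=1.5, cells_range=(100, 300), seed=7,
)
cohort, truth = cg.simulate_cohort(sim)
print(f"cohort: {cohort.n_subjects} subjects, {cohort.total_cells} cells, "
      f"{cohort.n_markers} markers, T={cohort.n_timepoints}")

config = benchmark_train_config(seed=7, epochs=15)
table, summary = cg.cross_validate(cohort, config)
print(table.to_string(index=False))
print(f"mean AUC {summary['auc']['mean']:.3f} (SD {summary['auc']['sd']:.3f})")
# AUC near 1 means held-out subjects' outcomes are recovered from their
# cells alone; with effect=0.0 the same pipeline drops to chance (~0.5).
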