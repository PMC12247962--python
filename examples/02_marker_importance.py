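"""Recover the outcome-informative markers with the mask explainer.

Trains on a synthetic cohort whose ground truth is known (markers M0-M2
carry the class signal), then optimizes Bernoulli keep-probabilities P_j
per marker under a lasso penalty: markers the frozen model needs keep
P near 1, the rest are driven toward 0.
"""

import cytogpnet as cg
from cytogpnet.data import subsample_cells
from cytogpnet.experiments import benchmark_sim_config, benchmark_train_config

cohort, truth = cg.simulate_cohort(benchmark_sim_config(seed=3, effect=1.5))
model = cg.fit(cohort, benchmark_train_config(seed=3, epochs=40, lr=0.05))

# a 20% cell subsample is ample for a global (sample-level) mask
importance = cg.explain(
    model, subsample_cells(cohort, 0.2, seed=3), lam=0.05, epochs=60, lr=0.15, seed=3
)
print(importance.table().to_string(index=False))
print(f"\ntrue informative markers: {['M%d' % j for j in truth.informative]}")
# P is the probability a marker must keep its measured values for the
# model's predictions to survive mean-imputation of the others.
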