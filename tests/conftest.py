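"""Shared fixtures: small synthetic cohorts and a fitted model.

Session-scoped so the (seconds-long) end-to-end fit is paid once and
reused by the trainer, explainer and evaluation tests.
"""

import numpy as np
import pytest

import cytogpnet as cg


def fast_config(**overrides) -> cg.TrainConfig:
    """Scaled-down training settings for second-scale test fits."""
    base = dict(
        pretrain_epochs=3,
        pretrain_batch_size=256,
        pretrain_lr=1e-3,
        pretrain_max_cells=6000,
        lr=5e-3,
        batch_size=10,
        epochs=10,
        mc_samples=3,
        n_inducing=16,
        lengthscale="median",
        seed=0,
    )
    base.update(overrides)
    return cg.TrainConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Separable two-timepoint cohort: 20 subjects, strong marker shift."""
    cfg = cg.SimConfig(
        n_subjects=20, n_timepoints=2, n_markers=6, n_populations=2,
        informative=(0, 1), effect=2.0, cells_range=(40, 80), seed=11,
    )
    cohort, truth = cg.simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def fitted(small_cohort):
    cohort, truth = small_cohort
    model = cg.fit(cohort, fast_config(epochs=60, lr=0.05))
    return model, cohort, truth
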