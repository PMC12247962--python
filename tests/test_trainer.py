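"""End-to-end training: determinism, invariances, raggedness, CV hygiene."""

import numpy as np
import pytest

import cytogpnet as cg
from cytogpnet.data import CellMatrix, ParameterError, assemble_cohort
from conftest import fast_config


def test_fit_logs_increasing_elbo(fitted):
    model, cohort, _ = fitted
    hist = model.history
    assert len(hist) == model.config.epochs
    # training ELBO improves substantially on a separable cohort
    assert hist[-1] > hist[0]
    assert hist[-1] - hist[0] >= 0.10 * abs(hist[0])


def test_fit_is_deterministic_under_seed(small_cohort):
    cohort, _ = small_cohort
    cfg = fast_config(epochs=2, seed=5)
    m1 = cg.fit(cohort, cfg)
    m2 = cg.fit(cohort, cfg)
    assert m1.history == m2.history
    p1 = cg.predict(m1, cohort)["probability"].to_numpy()
    p2 = cg.predict(m2, cohort)["probability"].to_numpy()
    np.testing.assert_array_equal(p1, p2)


def test_epochs_zero_returns_usable_pretrained_model(small_cohort):
    cohort, _ = small_cohort
    model = cg.fit(cohort, fast_config(epochs=0))
    assert model.history == []
    preds = cg.predict(model, cohort)
    assert len(preds) == cohort.n_subjects
    assert np.isfinite(preds["probability"]).all()


def test_prediction_invariant_to_cell_permutation(fitted):
    model, cohort, _ = fitted
    base = cg.predict(model, cohort)["probability"].to_numpy()
    rng = np.random.default_rng(0)
    shuffled = cg.Cohort(
        samples={
            k: CellMatrix(
                cm.values[rng.permutation(cm.n_cells)], cm.marker_names,
                cm.subject_id, cm.timepoint,
            )
            for k, cm in cohort.samples.items()
        },
        outcomes=dict(cohort.outcomes),
        n_timepoints=cohort.n_timepoints,
        marker_names=list(cohort.marker_names),
    )
    after = cg.predict(model, shuffled)["probability"].to_numpy()
    assert np.abs(after - base).max() <= 1e-6


def test_prediction_handles_extreme_cell_counts_and_missing_visits(fitted):
    """Ragged contract: cell counts 1 and 10,000 and a missing second visit
    must all yield finite probabilities with no subsampling or padding."""
    model, cohort, _ = fitted
    rng = np.random.default_rng(1)
    markers = cohort.marker_names
    samples = [
        CellMatrix(rng.normal(size=(1, 6)), markers, "tiny", 1),
        CellMatrix(rng.normal(size=(10, 6)), markers, "tiny", 2),
        CellMatrix(rng.normal(size=(10_000, 6)), markers, "huge", 1),
        CellMatrix(rng.normal(size=(10_000, 6)), markers, "huge", 2),
        CellMatrix(rng.normal(size=(25, 6)), markers, "onevisit", 1),
    ]
    probe = assemble_cohort(
        samples, {"tiny": 0, "huge": 1, "onevisit": 1}, n_timepoints=2
    )
    preds = cg.predict(model, probe)
    assert len(preds) == 3
    assert np.isfinite(preds["probability"]).all()
    assert ((preds["probability"] > 0) & (preds["probability"] < 1)).all()


def test_predict_rejects_schema_mismatch(fitted):
    model, cohort, _ = fitted
    bad = cg.Cohort(
        samples={
            k: CellMatrix(cm.values, [f"other{j}" for j in range(6)],
                          cm.subject_id, cm.timepoint)
            for k, cm in cohort.samples.items()
        },
        outcomes=dict(cohort.outcomes),
        n_timepoints=2,
        marker_names=[f"other{j}" for j in range(6)],
    )
    with pytest.raises(ParameterError, match="marker"):
        cg.predict(model, bad)


def test_gradients_reach_all_components(small_cohort):
    """One training step must move encoder, GP-variational, attention and
    head parameters (the decoder is pretraining-only and stays put)."""
    cohort, _ = small_cohort
    model0 = cg.fit(cohort, fast_config(epochs=0))
    model1 = cg.fit(cohort, fast_config(epochs=1))

    def arrays(m):
        return {
            "encoder_W0": m.ae.encoder[0][0].data,
            "mu_u": m.mu_u.data,
            "L_raw": m.L_raw.data,
            "Z": m.Z.data,
            "log_ls": m.log_ls.data,
            "attn_w_t1": m.attention.layers[1]["w"].data,
            "attn_w_t2": m.attention.layers[2]["w"].data,
            "head_W": m.head.W.data,
        }

    a0, a1 = arrays(model0), arrays(model1)
    for name in a0:
        assert not np.allclose(a0[name], a1[name]), f"{name} did not move"
    # decoder is not part of the ELBO: it must NOT move
    np.testing.assert_array_equal(
        model0.ae.decoder[0][0].data, model1.ae.decoder[0][0].data
    )


def test_ae_only_baseline_runs_and_shares_data_path(small_cohort):
    cohort, _ = small_cohort
    model = cg.fit(cohort, fast_config(epochs=5, baseline_mode="ae_only"))
    assert model.Z is None  # GP bypassed entirely
    preds = cg.predict(model, cohort)
    assert np.isfinite(preds["probability"]).all()


def test_cross_validate_subject_level_stratified(small_cohort):
    cohort, _ = small_cohort
    table, summary = cg.cross_validate(cohort, fast_config(epochs=3, folds=5))
    assert len(table) == 5
    assert set(summary) == {"auc", "f1", "precision", "recall"}
    assert 0.0 <= summary["auc"]["mean"] <= 1.0


def test_cross_validate_no_subject_straddles_folds(small_cohort):
    cohort, _ = small_cohort
    _, _, models = cg.cross_validate(
        cohort, fast_config(epochs=1, folds=4), return_models=True
    )
    test_sets = [set(ts) for _, ts in models]
    all_test = [s for ts in test_sets for s in ts]
    assert sorted(all_test) == cohort.subjects  # partition: each subject once
    for a in range(len(test_sets)):
        for b in range(a + 1, len(test_sets)):
            assert not (test_sets[a] & test_sets[b])


def test_covariates_enter_classification_head():
    rng = np.random.default_rng(7)
    markers = ["a", "b", "c", "d", "e"]
    samples, outcomes, covs = [], {}, {}
    for i in range(12):
        sid = f"S{i}"
        outcomes[sid] = i % 2
        covs[sid] = np.array([float(i % 2)])  # covariate perfectly predicts y
        samples.append(CellMatrix(rng.normal(size=(15, 5)), markers, sid, 1))
    cohort = assemble_cohort(samples, outcomes, covariates=covs, n_timepoints=1)
    model = cg.fit(cohort, fast_config(epochs=12, folds=2, lr=0.05))
    preds = cg.predict(model, cohort)
    rep = cg.compute_metrics(cohort.outcome_vector(), preds["probability"].to_numpy())
    assert rep.auc >= 0.9  # head exploited the covariate


def test_multiclass_softmax_head():
    cfg = cg.SimConfig(n_subjects=18, n_classes=3, n_markers=5, informative=(0, 1),
                       effect=1.5, cells_range=(20, 40), n_timepoints=1, seed=9)
    cohort, _ = cg.simulate_cohort(cfg)
    model = cg.fit(cohort, fast_config(epochs=5))
    assert model.head.link == "softmax"
    preds = cg.predict(model, cohort)
    probs = preds[[f"p_class{c}" for c in range(3)]].to_numpy()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
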