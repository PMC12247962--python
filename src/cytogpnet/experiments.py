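"""Reference benchmark experiments on synthetic cohorts.

These functions define the package's standard desk-scale study: a cohort of
N = 60 subjects at T = 2 timepoints, p = 10 markers, K = 3 Gaussian cell
populations, 3 informative markers shifted by delta = 1.5 in class-1
subjects, and 200-800 cells per sample.  Training settings are scaled to
this problem size (few pretraining epochs on a cell subsample, 15
fine-tuning epochs at learning rate 0.02, 32 inducing points, kernel
lengthscale initialized by the median-distance heuristic); the same
pipeline with the larger published-style settings is available through
:class:`~cytogpnet.trainer.TrainConfig` directly.

Every function takes a base seed and derives all randomness from it, so
results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from . import data as data_mod
from . import evaluation, explainer, svgp, trainer
from .synthetic import SimConfig, simulate_cohort


def benchmark_sim_config(seed: int, effect: float = 1.5, **overrides) -> SimConfig:
    base = dict(
        n_subjects=60, n_timepoints=2, n_markers=10, n_populations=3,
        informative=(0, 1, 2), effect=effect, cells_range=(200, 800), seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def benchmark_train_config(seed: int, **overrides) -> trainer.TrainConfig:
    base = dict(
        pretrain_epochs=4, pretrain_batch_size=256, pretrain_lr=1e-3,
        pretrain_max_cells=15_000,
        lr=0.02, batch_size=10, epochs=15, mc_samples=4,
        n_inducing=32, lengthscale="median",
        folds=5, stratified=True, seed=seed,
    )
    base.update(overrides)
    return trainer.TrainConfig(**base)


def _cv_auc(cohort, seed: int, protocol: str | None = None) -> float:
    _, summary = trainer.cross_validate(
        cohort, benchmark_train_config(seed), protocol=protocol
    )
    return summary["auc"]["mean"]


def signal_recovery(seed: int, n_seeds: int = 5) -> dict:
    """Median 5-fold CV AUC over seeds, for the signal and null cohorts."""
    seeds = [(seed + 1000 * i) % 2**31 for i in range(n_seeds)]
    signal, null = [], []
    for s in seeds:
        cohort, _ = simulate_cohort(benchmark_sim_config(s, effect=1.5))
        signal.append(_cv_auc(cohort, s))
        cohort0, _ = simulate_cohort(benchmark_sim_config(s, effect=0.0))
        null.append(_cv_auc(cohort0, s))
    return {
        "seeds": seeds,
        "signal_aucs": signal,
        "null_aucs": null,
        "signal_median_auc": float(np.median(signal)),
        "null_median_auc": float(np.median(null)),
    }


def robustness(seed: int, n_seeds: int = 3) -> dict:
    """Median CV AUC change under 50% cell subsampling and second-visit masking."""
    seeds = [(seed + 1000 * i) % 2**31 for i in range(n_seeds)]
    base, sub, mask = [], [], []
    for s in seeds:
        cohort, _ = simulate_cohort(benchmark_sim_config(s, effect=1.5))
        base.append(_cv_auc(cohort, s))
        sub.append(_cv_auc(cohort, s, protocol="subsample50"))
        mask.append(_cv_auc(cohort, s, protocol="mask_tp2"))
    return {
        "seeds": seeds,
        "base_aucs": base,
        "subsample50_aucs": sub,
        "mask_tp2_aucs": mask,
        "subsample50_auc_change": float(abs(np.median(sub) - np.median(base))),
        "mask_tp2_auc_change": float(abs(np.median(mask) - np.median(base))),
    }


def explainer_recovery(seed: int, n_runs: int = 10) -> dict:
    """Marker recovery by the mask explainer, plus the minimal-set check.

    One model is trained on the full signal cohort; the explainer is run
    ``n_runs`` times with different seeds on a 20% cell subsample (the mask
    objective needs sample-level, not cell-level, resolution).  Recovery
    succeeds when every informative marker outranks every uninformative one.
    The minimal-set check hard-masks only the uninformative markers and
    compares out-of-fold CV AUC with the unmasked folds.
    """
    cohort, truth = simulate_cohort(benchmark_sim_config(seed, effect=1.5))
    S = list(truth.informative)
    comp = [j for j in range(cohort.n_markers) if j not in S]

    config = benchmark_train_config(seed, epochs=40, lr=0.05)
    model = trainer.fit(cohort, config)
    explain_cohort = data_mod.subsample_cells(cohort, 0.2, seed=seed)
    successes, gaps = 0, []
    for i in range(n_runs):
        imp = explainer.explain(
            model, explain_cohort, lam=0.05, epochs=60, lr=0.15,
            seed=(seed + 77 * i) % 2**31,
        )
        gap = float(imp.P[S].min() - imp.P[comp].max())
        gaps.append(gap)
        successes += int(gap > 0)

    # minimal-set evaluation on held-out folds
    table, summary, models = trainer.cross_validate(
        cohort, benchmark_train_config(seed), return_models=True
    )
    keep = np.ones(cohort.n_markers)
    keep[comp] = 0.0  # mask only the uninformative markers
    masked_cohort = explainer.hard_mask_cohort(cohort, keep)
    masked_aucs = []
    for model_k, test_subjects in models:
        preds = trainer.predict(model_k, masked_cohort.subset_subjects(test_subjects))
        y = np.array([cohort.outcomes[s] for s in preds["subject_id"]])
        masked_aucs.append(
            evaluation.compute_metrics(y, preds["probability"].to_numpy()).auc
        )
    return {
        "recovery_successes": successes,
        "n_runs": n_runs,
        "recovery_rate": successes / n_runs,
        "gaps": gaps,
        "unmasked_cv_auc": summary["auc"]["mean"],
        "masked_noninformative_cv_auc": float(np.nanmean(masked_aucs)),
        "masked_auc_change": float(
            abs(np.nanmean(masked_aucs) - summary["auc"]["mean"])
        ),
    }


def batch_effect_diagnostic(seed: int, n_seeds: int = 3) -> dict:
    """Layer-wise Kruskal-Wallis batch heterogeneity on a batched cohort.

    Returns per-seed -log10 p at each layer and whether at least one seeded
    configuration shows lower heterogeneity at the attention layer than at
    the input layer (or attention-layer non-significance at 0.05).
    """
    results = []
    for i in range(n_seeds):
        s = (seed + 3000 * i) % 2**31
        sim = benchmark_sim_config(
            s, effect=1.5, n_subjects=30, cells_range=(100, 300),
            n_batches=3, batch_shift=1.0,
        )
        cohort, truth = simulate_cohort(sim)
        model = trainer.fit(cohort, benchmark_train_config(s, epochs=15))
        scores = evaluation.activation_scores(model, cohort)
        pvals = evaluation.batch_effect_pvalues(scores, truth.batch_of_subject)
        by_layer = dict(zip(pvals["layer"], pvals["neg_log10_p"]))
        p_by_layer = dict(zip(pvals["layer"], pvals["p"]))
        results.append(
            {
                "seed": s,
                "neg_log10_p": by_layer,
                "attenuated": bool(
                    by_layer["attention"] < by_layer["input"]
                    or p_by_layer["attention"] > 0.05
                ),
            }
        )
    return {"runs": results, "any_attenuated": any(r["attenuated"] for r in results)}


def svgp_oracle_check(seed: int) -> dict:
    """Variational-vs-exact GP agreement on the 1-d regression toy (n = 20)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-2, 2, size=(20, 1))
    kernel = svgp.SEKernel(lengthscale=0.8, variance=1.0)
    noise = 0.1
    y = np.sin(2 * X[:, 0]) + 0.2 * rng.standard_normal(20)
    mean_exact, log_ev = svgp.exact_gp_regression(X, y, X, kernel, noise)
    state = svgp.fit_gaussian_svgp(X, y, X.copy(), kernel, noise)
    post = svgp.marginal_variational_posterior(X, state, kernel)
    rms = float(np.sqrt(np.mean((post.mu_f - mean_exact) ** 2)))
    elbo_gap = float(abs(svgp.gaussian_elbo(X, y, state, kernel, noise) - log_ev))

    # marginal-posterior dense-integration agreement on 5-point instances
    max_err = 0.0
    for i in range(3):
        r = np.random.default_rng(seed + i)
        H = r.normal(size=(5, 2))
        Z = r.normal(size=(4, 2))
        A_ = r.normal(size=(4, 4))
        Sigma = A_ @ A_.T + 0.5 * np.eye(4)
        mu = r.normal(size=4)
        st = svgp.InducingState(Z=Z, mu=mu, L=np.linalg.cholesky(Sigma))
        post5 = svgp.marginal_variational_posterior(H, st, kernel, diag_only=False)
        Kzz = svgp.kernel_matrix(Z, Z, kernel) + 1e-6 * np.eye(4)
        Khz = svgp.kernel_matrix(H, Z, kernel)
        Khh = svgp.kernel_matrix(H, H, kernel)
        W = Khz @ np.linalg.inv(Kzz)
        mean_or = W @ mu
        cov_or = Khh - W @ Khz.T + W @ Sigma @ W.T
        max_err = max(
            max_err,
            float(np.abs(post5.mu_f - mean_or).max()),
            float(np.abs(post5.Sigma_f - cov_or).max()),
        )
    return {
        "predictive_mean_rms": rms,
        "elbo_gap": elbo_gap,
        "marginal_posterior_max_err": max_err,
    }


def permutation_and_raggedness_check(seed: int) -> dict:
    """Invariance of predictions to cell order; validity for extreme counts."""
    from .data import CellMatrix, assemble_cohort

    sim = benchmark_sim_config(seed, effect=1.5, n_subjects=16, cells_range=(50, 120))
    cohort, _ = simulate_cohort(sim)
    model = trainer.fit(cohort, benchmark_train_config(seed, epochs=5))

    base = trainer.predict(model, cohort)["probability"].to_numpy()
    rng = np.random.default_rng(seed)
    shuffled = data_mod.Cohort(
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
    after = trainer.predict(model, shuffled)["probability"].to_numpy()
    max_change = float(np.abs(after - base).max())

    probe_samples = []
    for name, m in [("c1", 1), ("c10", 10), ("c10000", 10_000)]:
        for t in (1, 2):
            probe_samples.append(
                CellMatrix(rng.normal(size=(m, cohort.n_markers)),
                           cohort.marker_names, name, t)
            )
    probe = assemble_cohort(
        probe_samples, {"c1": 0, "c10": 1, "c10000": 0}, n_timepoints=2
    )
    probs = trainer.predict(model, probe)["probability"].to_numpy()
    return {
        "max_permutation_change": max_change,
        "ragged_probs_finite": bool(np.isfinite(probs).all()),
        "ragged_cell_counts": [1, 10, 10_000],
    }
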