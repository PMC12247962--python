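"""End-to-end training: AE pretraining, ELBO maximization, cross-validation.

Fitting proceeds in two stages.  The autoencoder is first pretrained by
reconstruction on all training cells.  Then every parameter — encoder
weights, inducing inputs Z, kernel lengthscale, variational (mu, Sigma),
attention layers, and the classification head — is fine-tuned jointly by
maximizing the evidence lower bound with Adam.  Mini-batches are whole
subjects (all of a subject's cells across all timepoints), so attention
always pools complete samples; the likelihood term is rescaled by
N / batch_size to keep the full-data ELBO estimate unbiased, and the KL
term is added once per step.

The ``ae_only`` baseline shares the identical data path but bypasses the
GP: per-cell latent vectors feed the attention layers directly, giving a
controlled ablation of the GP component.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import autoencoder as ae_mod
from . import svgp
from ._autodiff import Adam, Tensor, concat, tensor
from .data import Cohort, ParameterError
from .predictor import (
    AttentionHead,
    ClassifierHead,
    attend_t,
    bce_from_logits,
    logits_t,
    softmax_ce_from_logits,
)


@dataclass
class TrainConfig:
    # AE pretraining (cytometry defaults)
    pretrain_epochs: int = 1000
    pretrain_batch_size: int = 128
    pretrain_lr: float = 1e-6
    pretrain_max_cells: int | None = None  # random cell subsample for pretraining
    ae_hidden: tuple[int, ...] = (16,)
    latent_dim: int = 4
    # end-to-end fine-tuning
    lr: float = 1e-4
    batch_size: int = 10
    epochs: int = 100
    mc_samples: int = 8  # B during training
    mc_samples_predict: int = 32
    # GP
    n_inducing: int = 100
    lengthscale: float | str = 0.1  # float, or "median" pairwise-distance heuristic
    variance: float = 1.0
    # attention / head
    attention_hidden: int = 8
    # evaluation
    folds: int = 5
    stratified: bool = True
    baseline_mode: str = "cytogpnet"  # {cytogpnet, ae_only}
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if self.batch_size < 1:
            raise ParameterError("batch size must be >= 1")
        if self.baseline_mode not in {"cytogpnet", "ae_only"}:
            raise ParameterError(f"unknown baseline_mode {self.baseline_mode!r}")


@dataclass
class FittedModel:
    """All trained components plus the training history and config fingerprint."""

    config: TrainConfig
    marker_names: list[str]
    n_timepoints: int
    n_classes: int
    n_covariates: int
    ae: ae_mod.AEParams
    attention: AttentionHead
    head: ClassifierHead
    # GP parts (absent in ae_only mode)
    Z: Tensor | None = None
    mu_u: Tensor | None = None
    L_raw: Tensor | None = None  # L = strict_tril(L_raw) + diag(exp(diag))
    log_ls: Tensor | None = None
    jitter: float = svgp.JITTER0_FACTOR
    history: list[float] = field(default_factory=list)  # per-epoch ELBO estimate
    pretrain_history: list[float] = field(default_factory=list)
    seed: int = 0

    # ---- numpy views ----------------------------------------------------
    @property
    def kernel(self) -> svgp.SEKernel:
        return svgp.SEKernel(
            lengthscale=float(np.exp(self.log_ls.data)), variance=self.config.variance
        )

    def _L(self) -> Tensor:
        O = self.Z.data.shape[0]
        mask = tensor(np.tril(np.ones((O, O)), -1))
        return self.L_raw * mask + self.L_raw.diag_part().exp().diag_embed()

    @property
    def inducing_state(self) -> svgp.InducingState:
        return svgp.InducingState(
            Z=self.Z.data.copy(), mu=self.mu_u.data.copy(), L=self._L().data.copy()
        )

    def parameters(self) -> list[Tensor]:
        ps = self.ae.parameters() + self.attention.parameters() + self.head.parameters()
        if self.Z is not None:
            ps += [self.Z, self.mu_u, self.L_raw, self.log_ls]
        return ps

    def parameter_checksum(self) -> float:
        return float(sum(np.sum(np.abs(p.data)) for p in self.parameters()))


# ---------------------------------------------------------------------------
# forward pass (shared by training, prediction and the explainer)
# ---------------------------------------------------------------------------

def _subject_logits(
    model: FittedModel,
    cohort: Cohort,
    subjects: list[str],
    sample_tensors: dict[tuple[str, int], Tensor],
    eps: np.ndarray | None,
    B: int,
) -> dict[str, Tensor]:
    """Logits per subject, shape (B,) sigmoid / (B, C) softmax.

    ``sample_tensors`` maps (subject, timepoint) to the cells x p input
    Tensor (constants for plain prediction, mask-perturbed graph nodes for
    the explainer).  ``eps=None`` gives the deterministic mu_f path.
    """
    keys = [
        (sid, t)
        for sid in subjects
        for t in range(1, cohort.n_timepoints + 1)
        if (sid, t) in sample_tensors
    ]
    H_all = concat([ae_mod.encode_t(sample_tensors[k], model.ae) for k in keys], axis=0)
    sizes = [sample_tensors[k].shape[0] for k in keys]
    offsets = np.cumsum([0] + sizes)

    if model.config.baseline_mode == "ae_only":
        f_all = H_all  # (m_tot, q); deterministic
        d = model.config.latent_dim
        B_eff = 1
    else:
        L = model._L()
        mu_f, var_f = svgp._marginal_diag_t(
            H_all, model.Z, model.mu_u, L, model.log_ls, model.config.variance,
            model.jitter,
        )
        if eps is None:
            f_flat = mu_f.reshape(1, -1)
            B_eff = 1
        else:
            f_flat = mu_f.reshape(1, -1) + var_f.sqrt().reshape(1, -1) * tensor(eps)
            B_eff = B
        d = 1

    logits: dict[str, Tensor] = {}
    zeros_feat = None
    for sid in subjects:
        feats = []
        for t in range(1, cohort.n_timepoints + 1):
            if (sid, t) in sample_tensors:
                i = keys.index((sid, t))
                a, b = offsets[i], offsets[i + 1]
                if model.config.baseline_mode == "ae_only":
                    seg = f_all[a:b, :].reshape(1, b - a, d)
                else:
                    seg = f_flat[:, a:b].reshape(B_eff, b - a, 1)
                pooled, _ = attend_t(seg, model.attention, t)  # (B,) or (B, q)
                if d == 1:
                    feats.append(pooled.reshape(B_eff, 1))
                else:
                    feats.append(pooled)
            else:
                if zeros_feat is None or zeros_feat.shape != (B_eff, d):
                    zeros_feat = tensor(np.zeros((B_eff, d)))
                feats.append(zeros_feat)  # zero padding for missing visits
        s = concat(feats, axis=1)  # (B, T*d)
        if cohort.covariates is not None:
            z = np.broadcast_to(cohort.covariates[sid], (B_eff, len(cohort.covariates[sid])))
            s = concat([s, tensor(np.array(z))], axis=1)
        logits[sid] = logits_t(s, model.head)
    return logits


def _nll(logits: Tensor, y: int, link: str) -> Tensor:
    if link == "sigmoid":
        return bce_from_logits(logits, y).mean()
    return softmax_ce_from_logits(logits, y).mean()


def _init_model(cohort: Cohort, config: TrainConfig, seed: int) -> FittedModel:
    """Pretrain the AE, initialize GP/attention/head."""
    p = cohort.n_markers
    ae_cfg = ae_mod.AEConfig(
        input_dim=p,
        hidden_dims=tuple(config.ae_hidden),
        latent_dim=config.latent_dim,
        seed=seed,
    )
    X_all = cohort.all_cells()
    X_pre = X_all
    if config.pretrain_max_cells is not None and X_all.shape[0] > config.pretrain_max_cells:
        sub = np.random.default_rng(seed + 7).choice(
            X_all.shape[0], size=config.pretrain_max_cells, replace=False
        )
        X_pre = X_all[sub]
    ae_params, pre_hist = ae_mod.pretrain(
        X_pre,
        ae_cfg,
        epochs=config.pretrain_epochs,
        batch_size=config.pretrain_batch_size,
        lr=config.pretrain_lr,
        seed=seed,
    )
    n_cov = (
        len(next(iter(cohort.covariates.values()))) if cohort.covariates else 0
    )
    n_classes = cohort.n_classes
    d = 1 if config.baseline_mode == "cytogpnet" else config.latent_dim
    attention = AttentionHead.init(
        cohort.n_timepoints, input_dim=d, hidden=config.attention_hidden, seed=seed + 1
    )
    head = ClassifierHead.init(
        cohort.n_timepoints * d + n_cov, n_classes=n_classes, seed=seed + 2
    )
    model = FittedModel(
        config=config,
        marker_names=list(cohort.marker_names),
        n_timepoints=cohort.n_timepoints,
        n_classes=n_classes,
        n_covariates=n_cov,
        ae=ae_params,
        attention=attention,
        head=head,
        pretrain_history=pre_hist,
        seed=seed,
    )
    if config.baseline_mode == "cytogpnet":
        H = ae_mod.encode(X_all, ae_params)
        Z0 = svgp.init_inducing_points(H, config.n_inducing, seed=seed + 3)
        if config.lengthscale == "median":
            rng = np.random.default_rng(seed + 4)
            sub = H[rng.choice(H.shape[0], size=min(500, H.shape[0]), replace=False)]
            d2 = svgp._sqdist(sub, sub)
            ls0 = float(np.sqrt(np.median(d2[d2 > 0]))) if (d2 > 0).any() else 1.0
        else:
            ls0 = float(config.lengthscale)
        kernel0 = svgp.SEKernel(lengthscale=ls0, variance=config.variance)
        state0 = svgp.InducingState.at_prior(Z0, kernel0)
        Kzz = svgp.kernel_matrix(Z0, Z0, kernel0)
        _, jit = svgp.stable_cholesky(Kzz, config.variance)
        L_raw0 = np.tril(state0.L, -1) + np.diag(np.log(np.diag(state0.L)))
        model.Z = tensor(Z0, requires_grad=True)
        model.mu_u = tensor(state0.mu, requires_grad=True)
        model.L_raw = tensor(L_raw0, requires_grad=True)
        model.log_ls = tensor(np.log(ls0), requires_grad=True)
        model.jitter = jit
    return model


def fit(cohort: Cohort, config: TrainConfig, seed: int | None = None) -> FittedModel:
    """Pretrain, then fine-tune end to end by maximizing the ELBO.

    Per-epoch ELBO estimates (minus the loss actually optimized) are logged
    in ``model.history``.  Deterministic under a fixed seed.
    """
    if cohort.n_subjects == 0:
        raise ParameterError("empty cohort")
    seed = config.seed if seed is None else seed
    model = _init_model(cohort, config, seed)
    if config.epochs == 0:
        return model

    rng = np.random.default_rng(seed + 10)
    params = model.parameters()
    opt = Adam(params, lr=config.lr)
    subjects = cohort.subjects
    N = len(subjects)
    y = cohort.outcomes
    B = config.mc_samples
    link = model.head.link

    for _ in range(config.epochs):
        order = rng.permutation(N)
        epoch_elbo = 0.0
        for start in range(0, N, config.batch_size):
            batch = [subjects[i] for i in order[start : start + config.batch_size]]
            sample_tensors = {
                (sid, t): tensor(cm.values)
                for sid in batch
                for t, cm in cohort.subject_samples(sid).items()
            }
            m_tot = sum(t.shape[0] for t in sample_tensors.values())
            eps = (
                rng.standard_normal((B, m_tot))
                if config.baseline_mode == "cytogpnet"
                else None
            )
            logits = _subject_logits(model, cohort, batch, sample_tensors, eps, B)
            nll = None
            for sid in batch:
                term = _nll(logits[sid], y[sid], link)
                nll = term if nll is None else nll + term
            loss = nll * (N / len(batch))
            if config.baseline_mode == "cytogpnet":
                eye = tensor(np.eye(model.Z.shape[0]))
                loss = loss + svgp._kl_t(
                    model.mu_u, model._L(), model.Z, model.log_ls,
                    config.variance, model.jitter, eye,
                )
            if not np.isfinite(loss.data):
                raise ae_mod.DivergenceError("non-finite ELBO during fine-tuning")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_elbo += -float(loss.data) * len(batch) / N
        model.history.append(epoch_elbo)
    return model


def elbo(cohort: Cohort, model: FittedModel, B: int = 32, seed: int = 0) -> float:
    """Monte Carlo estimate of the full-data ELBO under the current model."""
    subjects = cohort.subjects
    sample_tensors = {
        (sid, t): tensor(cm.values)
        for sid in subjects
        for t, cm in cohort.subject_samples(sid).items()
    }
    m_tot = sum(t.shape[0] for t in sample_tensors.values())
    rng = np.random.default_rng(seed)
    eps = (
        rng.standard_normal((B, m_tot))
        if model.config.baseline_mode == "cytogpnet"
        else None
    )
    logits = _subject_logits(model, cohort, subjects, sample_tensors, eps, B)
    total = sum(
        float(_nll(logits[sid], cohort.outcomes[sid], model.head.link).data)
        for sid in subjects
    )
    kl = (
        svgp.kl_term(model.inducing_state, model.kernel)
        if model.config.baseline_mode == "cytogpnet"
        else 0.0
    )
    return -total - kl


def predict(model: FittedModel, cohort: Cohort) -> "pd.DataFrame":
    """Deterministic per-subject probabilities using the posterior mean mu_f."""
    import pandas as pd

    if list(cohort.marker_names) != list(model.marker_names):
        diff = set(cohort.marker_names) ^ set(model.marker_names)
        raise ParameterError(f"marker schema mismatch; differing markers: {sorted(diff)}")
    subjects = cohort.subjects
    sample_tensors = {
        (sid, t): tensor(cm.values)
        for sid in subjects
        for t, cm in cohort.subject_samples(sid).items()
    }
    logits = _subject_logits(model, cohort, subjects, sample_tensors, eps=None, B=1)
    rows = []
    for sid in subjects:
        z = logits[sid].data
        if model.head.link == "sigmoid":
            prob = float(1.0 / (1.0 + np.exp(-z.ravel()[0])))
            rows.append({"subject_id": sid, "probability": prob, "label": int(prob >= 0.5)})
        else:
            zz = z.reshape(-1)
            e = np.exp(zz - zz.max())
            probs = e / e.sum()
            row = {"subject_id": sid, "label": int(np.argmax(probs))}
            row.update({f"p_class{c}": float(p) for c, p in enumerate(probs)})
            rows.append(row)
    return pd.DataFrame(rows)


def cross_validate(
    cohort: Cohort,
    config: TrainConfig,
    protocol: str | None = None,
    return_models: bool = False,
):
    """Subject-level (optionally stratified) k-fold cross-validation.

    No subject straddles train/test, and all fitting — AE pretraining,
    inducing initialization, fine-tuning — sees only the fold's training
    subjects.  ``protocol`` applies a robustness variant to the cohort
    before CV: ``"subsample50"`` (keep 50% of each sample's cells) or
    ``"mask_tp2"`` (drop the second visit for 10% of subjects).

    Returns (per-fold metrics DataFrame, summary dict); with
    ``return_models=True`` also a list of (model, test_subjects) per fold.
    """
    import pandas as pd

    from . import data as data_mod
    from .evaluation import compute_metrics

    if protocol == "subsample50":
        cohort = data_mod.subsample_cells(cohort, 0.5, seed=config.seed)
    elif protocol == "mask_tp2":
        cohort = data_mod.mask_timepoint(cohort, 2, 0.1, seed=config.seed)
    elif protocol is not None:
        raise ParameterError(f"unknown protocol {protocol!r}")

    subjects = np.array(cohort.subjects)
    y = cohort.outcome_vector()
    if len(subjects) < config.folds:
        raise ParameterError("need at least as many subjects as folds")

    from sklearn.model_selection import KFold, StratifiedKFold

    min_class = np.bincount(y).min()
    if config.stratified and min_class >= config.folds:
        splitter = StratifiedKFold(config.folds, shuffle=True, random_state=config.seed % 2**31)
        splits = splitter.split(subjects, y)
    else:
        splitter = KFold(config.folds, shuffle=True, random_state=config.seed % 2**31)
        splits = splitter.split(subjects)

    rows, models = [], []
    for k, (tr, te) in enumerate(splits):
        train_subjects = subjects[tr].tolist()
        test_subjects = subjects[te].tolist()
        fold_seed = config.seed + k  # per-fold reinitialization
        model = fit(cohort.subset_subjects(train_subjects), config, seed=fold_seed)
        preds = predict(model, cohort.subset_subjects(test_subjects))
        y_te = np.array([cohort.outcomes[s] for s in preds["subject_id"]])
        if model.head.link == "sigmoid":
            scores = preds["probability"].to_numpy()
        else:
            scores = preds["label"].to_numpy().astype(float)
        rep = compute_metrics(y_te, scores)
        rows.append(
            {"fold": k, "auc": rep.auc, "f1": rep.f1,
             "precision": rep.precision, "recall": rep.recall}
        )
        if return_models:
            models.append((model, test_subjects))
    table = pd.DataFrame(rows)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN folds
        summary = {
            m: {"mean": float(np.nanmean(table[m])), "sd": float(np.nanstd(table[m]))}
            for m in ["auc", "f1", "precision", "recall"]
        }
    if return_models:
        return table, summary, models
    return table, summary


def clone_config(config: TrainConfig, **overrides) -> TrainConfig:
    return replace(copy.deepcopy(config), **overrides)
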