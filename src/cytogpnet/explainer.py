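"""Post-hoc global marker importance by learned column masking.

The question the explainer answers: which minimal set of markers must keep
their measured values for the trained model's predictions to survive?  A
mask vector assigns every marker j a Bernoulli(P_j) keep-probability; a
sampled mask perturbs the data as

    Xm = X * m + Xbar * (1 - m)

replacing masked-out columns by their mean over the analysis set's cells
(one shared mask value per column).  P is optimized to minimize the
masked-prediction loss plus a lasso penalty lambda * sum_j P_j that drives
uninformative markers' probabilities to zero.  Bernoulli sampling is made
differentiable through the binary-concrete (Gumbel-Softmax) relaxation

    m_j = sigmoid((logit(P_j) + logit(e_j)) / tau),  e_j ~ U(0, 1)

with the temperature tau annealed geometrically over the run.  The model
itself stays frozen; the final P_j are the global importance scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, tensor
from .data import CellMatrix, Cohort, ParameterError
from .trainer import FittedModel, _nll, _subject_logits

_EPS = 1e-6


@dataclass
class MaskImportance:
    """Final per-marker keep-probabilities plus the optimization record."""

    P: np.ndarray
    marker_names: list[str]
    lam: float
    trace: list[float] = field(default_factory=list)
    temperature_schedule: tuple[float, float] = (1.0, 0.1)
    seed: int = 0

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"marker": self.marker_names, "P": self.P})
        df["rank"] = df["P"].rank(ascending=False, method="min").astype(int)
        return df.sort_values("rank").reset_index(drop=True)


def perturb(X: np.ndarray, mask_columns: np.ndarray, column_means: np.ndarray) -> np.ndarray:
    """Blend each column toward its analysis-set mean: m*X + (1-m)*Xbar."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mask_columns = np.asarray(mask_columns, dtype=float)
    column_means = np.asarray(column_means, dtype=float)
    if mask_columns.shape != (X.shape[1],) or column_means.shape != (X.shape[1],):
        raise ParameterError(
            f"mask and means must have length {X.shape[1]}, got "
            f"{mask_columns.shape} and {column_means.shape}"
        )
    return X * mask_columns + column_means * (1.0 - mask_columns)


def sample_relaxed_mask(P: np.ndarray, temperature: float, seed=None) -> np.ndarray:
    """One binary-concrete sample per column; differentiable in P, seeded."""
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = np.clip(np.asarray(P, dtype=float), _EPS, 1 - _EPS)
    e = np.clip(rng.uniform(size=P.shape), _EPS, 1 - _EPS)
    logits = (np.log(P / (1 - P)) + np.log(e / (1 - e))) / temperature
    return 1.0 / (1.0 + np.exp(-logits))


def _relaxed_mask_t(theta: Tensor, e: np.ndarray, temperature: float) -> Tensor:
    """Differentiable mask from unconstrained logits theta (P = sigmoid(theta))."""
    noise = tensor(np.log(e / (1.0 - e)))
    return ((theta + noise) / temperature).sigmoid()


def explain(
    model: FittedModel,
    cohort: Cohort,
    lam: float = 0.01,
    epochs: int = 80,
    lr: float = 0.05,
    seed: int = 0,
    timepoint: int | None = None,
    temperature: tuple[float, float] = (1.0, 0.1),
    cell_subset: dict[tuple[str, int], np.ndarray] | None = None,
    average_last: int = 10,
) -> MaskImportance:
    """Optimize the global mask probabilities against the frozen model.

    ``timepoint`` restricts masking to one visit's data (markers at other
    visits pass through unmasked), supporting baseline-vs-post-treatment
    analyses.  ``cell_subset`` maps sample keys to boolean row masks; only
    those cells are perturbed and column means are recomputed within the
    subset.  The reported P averages the per-epoch probabilities over the
    final ``average_last`` epochs, damping the stochastic-mask jitter of
    the last iterates.  Model parameters are never modified.
    """
    import warnings

    if lam <= 0:
        warnings.warn("lambda <= 0: no sparsity pressure on the mask")
    p = len(model.marker_names)
    rng = np.random.default_rng(seed)
    subjects = cohort.subjects

    # analysis-set column means (per sample selection rules)
    selected: list[np.ndarray] = []
    for key in sorted(cohort.samples):
        if timepoint is not None and key[1] != timepoint:
            continue
        vals = cohort.samples[key].values
        if cell_subset is not None:
            vals = vals[cell_subset.get(key, np.zeros(len(vals), dtype=bool))]
        if len(vals):
            selected.append(vals)
    if not selected:
        raise ParameterError("no cells selected for explanation")
    means = tensor(np.vstack(selected).mean(axis=0))

    theta = tensor(np.zeros(p), requires_grad=True)  # P = sigmoid(0) = 0.5
    opt = Adam([theta], lr=lr)
    t_hi, t_lo = temperature
    trace: list[float] = []
    p_tail: list[np.ndarray] = []
    y = cohort.outcomes
    link = model.head.link
    B = model.config.mc_samples

    for epoch in range(epochs):
        tau = t_hi * (t_lo / t_hi) ** (epoch / max(epochs - 1, 1))
        e = np.clip(rng.uniform(size=p), _EPS, 1 - _EPS)
        mask = _relaxed_mask_t(theta, e, tau)
        sample_tensors: dict[tuple[str, int], Tensor] = {}
        for key in sorted(cohort.samples):
            cm = cohort.samples[key]
            Xt = tensor(cm.values)
            apply_here = timepoint is None or key[1] == timepoint
            if apply_here and cell_subset is not None:
                rows = cell_subset.get(key, np.zeros(cm.n_cells, dtype=bool))
                apply_here = rows.any()
            if not apply_here:
                sample_tensors[key] = Xt
                continue
            masked = Xt * mask + means * (1.0 - mask)
            if cell_subset is not None:
                rows = cell_subset.get(key, np.zeros(cm.n_cells, dtype=bool))
                sel = tensor(rows.astype(float)[:, None])
                masked = masked * sel + Xt * (1.0 - sel)
            sample_tensors[key] = masked
        m_tot = sum(t_.shape[0] for t_ in sample_tensors.values())
        eps = (
            rng.standard_normal((B, m_tot))
            if model.config.baseline_mode == "cytogpnet"
            else None
        )
        logits = _subject_logits(model, cohort, subjects, sample_tensors, eps, B)
        loss = None
        for sid in subjects:
            term = _nll(logits[sid], y[sid], link)
            loss = term if loss is None else loss + term
        loss = loss / len(subjects) + lam * theta.sigmoid().sum()
        if not np.isfinite(loss.data):
            raise RuntimeError("explainer objective diverged")
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if epoch >= epochs - max(average_last, 1):
            p_tail.append(1.0 / (1.0 + np.exp(-theta.data)))

    P = np.mean(p_tail, axis=0)
    return MaskImportance(
        P=P, marker_names=list(model.marker_names), lam=lam, trace=trace,
        temperature_schedule=temperature, seed=seed,
    )


def explain_subset(
    model: FittedModel,
    cohort: Cohort,
    cell_subset_labels: dict[tuple[str, int], np.ndarray],
    lam: float = 0.01,
    **kwargs,
) -> dict[str, MaskImportance]:
    """Run the explainer once per labeled cell subset.

    ``cell_subset_labels`` maps sample keys to per-cell string labels (e.g.
    gated population names).  Column means are recomputed within each
    subset; empty subsets are skipped with a warning.
    """
    import warnings

    labels = sorted(
        {str(v) for arr in cell_subset_labels.values() for v in np.unique(arr)}
    )
    out: dict[str, MaskImportance] = {}
    for lab in labels:
        subset = {
            key: np.asarray(arr).astype(str) == lab
            for key, arr in cell_subset_labels.items()
        }
        if not any(m.any() for m in subset.values()):
            warnings.warn(f"subset {lab!r} is empty; skipped")
            continue
        out[lab] = explain(model, cohort, lam=lam, cell_subset=subset, **kwargs)
    return out


def lambda_sweep(
    model: FittedModel,
    cohort: Cohort,
    lambdas=(0.01, 0.02, 0.05, 0.1),
    **kwargs,
) -> pd.DataFrame:
    """Importance scores across a grid of penalty weights.

    The penalty trades prediction fidelity against mask sparsity; sweeping
    it shows which markers survive increasing pressure.  Returns a tidy
    frame (lambda, marker, P).
    """
    rows = []
    for lam in lambdas:
        imp = explain(model, cohort, lam=lam, **kwargs)
        for name, p in zip(imp.marker_names, imp.P):
            rows.append({"lambda": lam, "marker": name, "P": float(p)})
    return pd.DataFrame(rows)


def hard_mask_cohort(cohort: Cohort, keep: np.ndarray) -> Cohort:
    """Apply a binary mask to every sample (masked columns -> cohort mean)."""
    keep = np.asarray(keep, dtype=float)
    means = cohort.all_cells().mean(axis=0)
    samples = {
        key: CellMatrix(
            perturb(cm.values, keep, means), cm.marker_names, cm.subject_id, cm.timepoint
        )
        for key, cm in cohort.samples.items()
    }
    return Cohort(
        samples=samples,
        outcomes=dict(cohort.outcomes),
        n_timepoints=cohort.n_timepoints,
        covariates=cohort.covariates,
        marker_names=list(cohort.marker_names),
    )
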