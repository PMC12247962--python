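"""Classification metrics and the layer-wise batch-effect diagnostic.

AUC follows the rank/concordance definition (tied scores count half), so a
constant score vector gives exactly 0.5.  F1, precision and recall are
computed at a 0.5 probability threshold; undefined cases (e.g. no predicted
positives) are reported as missing (NaN), never as zero.

The batch diagnostic summarizes each sample at each model stage — input,
AE latent, GP output, attention output — by one scalar activation score
(the mean over the sample's cells and output dimensions), then quantifies
cross-batch heterogeneity of those scores with the Kruskal-Wallis rank
test.  A drop in -log10 p from input to attention indicates the network
attenuates batch structure while it extracts outcome signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Cohort, ParameterError


@dataclass
class MetricsReport:
    auc: float  # NaN when undefined (single-class truth)
    f1: float
    precision: float
    recall: float
    confusion: np.ndarray | None = None


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties (via midranks)."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def compute_metrics(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """AUC plus thresholded F1/precision/recall for binary outcomes."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ParameterError("y_true and scores must have equal length")
    if not set(np.unique(y_true)) <= {0, 1}:
        raise ParameterError("compute_metrics expects binary labels")
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: AUC undefined, reported as NaN")
    auc = _rank_auc(y_true, scores)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan") if (np.isnan(precision) or np.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    confusion = np.array([[tn, fp], [fn, tp]])
    return MetricsReport(auc=auc, f1=f1, precision=precision, recall=recall,
                         confusion=confusion)


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Multiclass confusion matrix; rows = true class, columns = predicted."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    C = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((C, C), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical values across groups return (0, 1) with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ParameterError("need >= 2 nonempty groups")
    allv = np.concatenate(groups)
    if np.allclose(allv, allv[0]):
        warnings.warn("all values identical: H = 0, p = 1 by convention")
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


LAYERS = ("input", "ae", "gp", "attention")


def activation_scores(model, cohort: Cohort) -> pd.DataFrame:
    """Per-sample scalar summaries at each stage of the network.

    For input/AE/GP layers the score is the mean over the sample's cells
    and output dimensions; the attention layer's score is the pooled scalar
    s_nt itself.  Returns a tidy frame with one row per (sample, layer).
    """
    from . import autoencoder as ae_mod
    from . import svgp
    from ._autodiff import tensor
    from .predictor import attend_t

    rows = []
    state = model.inducing_state if model.Z is not None else None
    kernel = model.kernel if model.Z is not None else None
    for (sid, t) in sorted(cohort.samples):
        cm = cohort.samples[(sid, t)]
        X = cm.values
        H = ae_mod.encode(X, model.ae)
        rows.append((sid, t, "input", float(X.mean())))
        rows.append((sid, t, "ae", float(H.mean())))
        if state is not None:
            post = svgp.marginal_variational_posterior(H, state, kernel)
            f = post.mu_f
            rows.append((sid, t, "gp", float(f.mean())))
            pooled, _ = attend_t(tensor(f.reshape(1, -1, 1)), model.attention, t)
            rows.append((sid, t, "attention", float(pooled.data.ravel()[0])))
        else:
            pooled, _ = attend_t(tensor(H.reshape(1, *H.shape)), model.attention, t)
            rows.append((sid, t, "attention", float(np.mean(pooled.data))))
    return pd.DataFrame(rows, columns=["subject_id", "timepoint", "layer", "score"])


def batch_effect_pvalues(
    scores: pd.DataFrame, batch_of_subject: dict[str, int]
) -> pd.DataFrame:
    """Kruskal-Wallis p-value of activation scores across batches, per layer."""
    rows = []
    for layer, sub in scores.groupby("layer"):
        groups = [
            g["score"].to_numpy()
            for _, g in sub.groupby(sub["subject_id"].map(batch_of_subject))
        ]
        H, p = kruskal_wallis(groups)
        rows.append({"layer": layer, "H": H, "p": p, "neg_log10_p": -np.log10(max(p, 1e-300))})
    out = pd.DataFrame(rows)
    order = {name: i for i, name in enumerate(LAYERS)}
    return out.sort_values("layer", key=lambda s: s.map(order)).reset_index(drop=True)
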