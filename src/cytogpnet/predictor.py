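"""Attention pooling per timepoint and the subject-level classification head.

Each visit's per-cell GP outputs are pooled to one scalar s_nt by gated
attention: cell i gets score e_i = w^T (tanh(V f_i) * sigmoid(U f_i)),
weights are the softmax of the scores, and s_nt is the weighted sum of the
f values.  The weights are nonnegative, sum to one, and the pooled value is
invariant to cell order and defined for any number of cells >= 1.  One
attention layer is learned per timepoint; the T pooled scalars concatenate
into the subject representation s_n, with missing visits zero-padded.

The head is logistic over s_n (plus optional subject covariates):
p(y=1 | s) = sigmoid(w^T s + c^T z + b); for multiclass outcomes a softmax
over per-class linear scores replaces the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, tensor
from .data import ParameterError


@dataclass
class AttentionHead:
    """Per-timepoint gated-attention parameters, shared across subjects."""

    n_timepoints: int
    input_dim: int = 1  # 1 for GP scalars; q for the AE-only baseline
    hidden: int = 8
    layers: dict[int, dict[str, Tensor]] = field(default_factory=dict)

    @classmethod
    def init(cls, n_timepoints: int, input_dim: int = 1, hidden: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        head = cls(n_timepoints=n_timepoints, input_dim=input_dim, hidden=hidden)
        s = np.sqrt(1.0 / max(input_dim, 1))
        for t in range(1, n_timepoints + 1):
            head.layers[t] = {
                "V": tensor(rng.normal(0, s, size=(input_dim, hidden)), requires_grad=True),
                "U": tensor(rng.normal(0, s, size=(input_dim, hidden)), requires_grad=True),
                "w": tensor(rng.normal(0, np.sqrt(1.0 / hidden), size=hidden), requires_grad=True),
            }
        return head

    def parameters(self) -> list[Tensor]:
        return [p for lay in self.layers.values() for p in lay.values()]


def attend_t(f: Tensor, head: AttentionHead, timepoint: int) -> tuple[Tensor, Tensor]:
    """Pool per-cell values for one visit.

    ``f`` has shape (..., m, d): trailing axes are cells x input-dim, with an
    optional leading Monte Carlo axis.  Returns (pooled (...,) x d, weights).
    """
    lay = head.layers[timepoint]
    gate = (f @ lay["V"]).tanh() * (f @ lay["U"]).sigmoid()
    scores = gate @ lay["w"]  # (..., m)
    weights = scores.softmax(axis=-1)
    if head.input_dim == 1:
        pooled = (weights * f.reshape(*f.shape[:-1])).sum(axis=-1)
    else:
        pooled = (weights.reshape(*weights.shape, 1) * f).sum(axis=-2)
    return pooled, weights


def attend(f_values: np.ndarray, head: AttentionHead, timepoint: int) -> tuple[float, np.ndarray]:
    """Numpy front end for one sample's m-vector of GP outputs."""
    f_values = np.asarray(f_values, dtype=np.float64)
    if f_values.ndim == 1:
        f_values = f_values[:, None]
    if f_values.shape[0] == 0:
        raise ParameterError(
            "cannot pool an empty cell set; missing visits are zero-padded upstream"
        )
    pooled, w = attend_t(tensor(f_values), head, timepoint)
    return (float(pooled.data) if head.input_dim == 1 else pooled.data), w.data


def subject_representation(
    per_timepoint: dict[int, float], n_timepoints: int
) -> np.ndarray:
    """Concatenate pooled scalars into s_n; absent visits contribute 0."""
    if not per_timepoint:
        raise ParameterError("subject has no observed timepoints")
    return np.array(
        [per_timepoint.get(t, 0.0) for t in range(1, n_timepoints + 1)], dtype=np.float64
    )


@dataclass
class ClassifierHead:
    """Linear head over s_n and covariates with a sigmoid or softmax link."""

    link: str  # {sigmoid, softmax}
    W: Tensor  # (T + n_cov,) for sigmoid; (C, T + n_cov) for softmax
    b: Tensor  # scalar for sigmoid; (C,) for softmax

    @classmethod
    def init(cls, n_features: int, n_classes: int = 2, seed: int = 0) -> "ClassifierHead":
        rng = np.random.default_rng(seed)
        if n_classes == 2:
            return cls(
                link="sigmoid",
                W=tensor(rng.normal(0, 0.1, size=n_features), requires_grad=True),
                b=tensor(0.0, requires_grad=True),
            )
        return cls(
            link="softmax",
            W=tensor(rng.normal(0, 0.1, size=(n_classes, n_features)), requires_grad=True),
            b=tensor(np.zeros(n_classes), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def logits_t(s: Tensor, head: ClassifierHead) -> Tensor:
    """(..., n_features) -> logits: (...,) for sigmoid, (..., C) for softmax."""
    if head.link == "sigmoid":
        return s @ head.W + head.b
    return s @ head.W.T + head.b


def predict_proba(
    s_n: np.ndarray, head: ClassifierHead, covariates: np.ndarray | None = None
) -> np.ndarray | float:
    """Outcome probability (binary) or class-probability vector from s_n."""
    s = np.asarray(s_n, dtype=np.float64)
    if covariates is not None:
        s = np.concatenate([s, np.asarray(covariates, dtype=np.float64)])
    n_feat = head.W.shape[-1] if head.link == "softmax" else head.W.shape[0]
    if s.shape[-1] != n_feat:
        raise ParameterError(f"head expects {n_feat} features, got {s.shape[-1]}")
    z = logits_t(tensor(s), head)
    if head.link == "sigmoid":
        return float(z.sigmoid().data)
    return z.softmax(axis=-1).data


def bce_from_logits(logit: Tensor, y: float) -> Tensor:
    """Numerically stable binary cross-entropy: softplus(z) - y*z."""
    return logit.softplus() - logit * float(y)


def softmax_ce_from_logits(logits: Tensor, y: int) -> Tensor:
    """Categorical cross-entropy over the trailing class axis (stable log-sum-exp)."""
    shift = logits.data.max(axis=-1, keepdims=True)
    lse = (logits - shift).exp().sum(axis=-1).log() + tensor(np.squeeze(shift, axis=-1))
    return lse - logits[..., int(y)]


__all__ = [
    "AttentionHead",
    "ClassifierHead",
    "attend",
    "attend_t",
    "subject_representation",
    "predict_proba",
    "logits_t",
    "bce_from_logits",
    "softmax_ce_from_logits",
]
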