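"""Preprocessing pathways: arcsinh for cytometry, filter/normalize/log1p/HVG for scRNA-seq.

Cytometry intensities go through ``y = arcsinh(x / c)``: logarithmic for large
values, linear near zero, and well defined for the zero and small negative
values that compensation produces.  The cofactor ``c`` sets the width of the
linear region: 5 is the standard choice for mass cytometry (CyTOF), 150 for
fluorescence flow cytometry.

scRNA-seq counts are (i) filtered to genes detected in at least
``min_cells_per_gene`` cells, (ii) depth-normalized so each cell totals
``target_depth``, (iii) log1p-transformed, and (iv) reduced to the
``n_hvg`` most variable genes, which become the marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import CellMatrix, ParameterError

_MODE_COFACTORS = {"cytof": 5.0, "flow": 150.0}


@dataclass
class PreprocessConfig:
    mode: str = "cytof"  # {cytof, flow, scrnaseq}
    cofactor: float | None = None  # default resolved from mode
    min_cells_per_gene: int = 10
    target_depth: float = 10_000.0
    n_hvg: int = 1_000

    def __post_init__(self):
        if self.mode not in {"cytof", "flow", "scrnaseq"}:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.cofactor is None:
            self.cofactor = _MODE_COFACTORS.get(self.mode, 5.0)
        if self.cofactor <= 0:
            raise ParameterError(f"cofactor must be > 0, got {self.cofactor}")
        if self.n_hvg < 1 or self.target_depth <= 0:
            raise ParameterError("n_hvg must be >= 1 and target_depth > 0")


def arcsinh_transform(X, cofactor: float):
    """``y = arcsinh(x / c) = ln(x/c + sqrt((x/c)^2 + 1))``, entrywise.

    Accepts a :class:`CellMatrix` or a plain array and returns the same
    type.  Strictly monotone and odd; inverse is ``x = c * sinh(y)``.
    """
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be > 0, got {cofactor}")
    if isinstance(X, CellMatrix):
        return CellMatrix(
            np.arcsinh(X.values / cofactor), X.marker_names, X.subject_id, X.timepoint
        )
    return np.arcsinh(np.asarray(X, dtype=np.float64) / cofactor)


def inverse_arcsinh(Y, cofactor: float):
    """Inverse of :func:`arcsinh_transform`."""
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be > 0, got {cofactor}")
    return cofactor * np.sinh(np.asarray(Y, dtype=np.float64))


def select_hvg(log_expr: np.ndarray, n_hvg: int) -> np.ndarray:
    """Indices of the ``n_hvg`` highest-variance genes of a cells x genes matrix.

    The dispersion statistic is the per-gene variance of the log1p-normalized
    expression; ties break toward the lower gene index.  Returned indices are
    in ascending order so that column order is preserved downstream.
    """
    log_expr = np.asarray(log_expr, dtype=np.float64)
    if n_hvg > log_expr.shape[1]:
        raise ParameterError(
            f"n_hvg={n_hvg} exceeds the {log_expr.shape[1]} available genes"
        )
    var = log_expr.var(axis=0)
    order = np.argsort(-var, kind="stable")  # stable: ties keep ascending index
    return np.sort(order[:n_hvg])


def preprocess_scrnaseq(
    counts,
    config: PreprocessConfig | None = None,
    gene_names: list[str] | None = None,
    subject_id: str = "",
    timepoint: int = 1,
) -> CellMatrix:
    """Run the scRNA-seq chain: gene filter -> depth normalize -> log1p -> HVG.

    ``counts`` is a dense or sparse nonnegative cells x genes matrix.  A cell
    with zero total count cannot be depth-normalized and raises an error.
    """
    config = config or PreprocessConfig(mode="scrnaseq")
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2:
        raise ParameterError("counts must be 2-d (cells x genes)")
    if (counts < 0).any():
        raise ParameterError("counts must be nonnegative")
    n_cells, n_genes = counts.shape
    if gene_names is None:
        gene_names = [f"gene{j}" for j in range(n_genes)]

    # (i) gene filter: expressed in >= min_cells_per_gene cells
    detected = (counts > 0).sum(axis=0)
    keep = detected >= config.min_cells_per_gene
    if not keep.any():
        raise ParameterError("no gene passes the detection filter")
    counts = counts[:, keep]
    gene_names = [g for g, k in zip(gene_names, keep) if k]

    # (ii) per-cell depth normalization to target_depth
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ParameterError(
            f"cell(s) {zero[:5].tolist()} have zero total count after gene "
            "filtering and cannot be depth-normalized"
        )
    norm = counts * (config.target_depth / totals)[:, None]

    # (iii) log1p
    logged = np.log1p(norm)

    # (iv) HVG selection
    idx = select_hvg(logged, config.n_hvg)
    return CellMatrix(
        logged[:, idx], [gene_names[j] for j in idx], subject_id, timepoint
    )
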