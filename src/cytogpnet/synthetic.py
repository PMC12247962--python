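"""Synthetic longitudinal cytometry cohorts with known ground truth.

Each subject carries a binary (or multiclass) outcome; every present visit
yields a cells x markers matrix drawn from a K-component Gaussian mixture
on an arcsinh-like scale (values are treated as already preprocessed, so
simulated cohorts feed the model directly).  Outcome information enters as
a mean shift of ``effect`` on a designated set of informative markers for
class-1 subjects.  Optional additive batch shifts and missing visits mimic
the common nuisance structure of multi-run studies.

The returned ground-truth record (labels, informative set, effect size,
batch assignment, per-cell population labels) lets marker-recovery and
calibration experiments be scored automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CellMatrix, Cohort, ParameterError


@dataclass
class SimConfig:
    n_subjects: int = 60
    n_timepoints: int = 2
    n_markers: int = 10
    n_populations: int = 3
    informative: tuple[int, ...] = (0, 1, 2)
    effect: float = 1.5
    cells_range: tuple[int, int] = (200, 800)
    mixture_weights: tuple[float, ...] | None = None  # shared by both classes
    population_spread: float = 1.0
    shift_timepoints: tuple[int, ...] | None = None  # None = all timepoints
    n_batches: int = 1
    batch_shift: float = 0.0
    missing_prob: float = 0.0
    class_balance: float = 0.5
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.mixture_weights is None:
            w = np.arange(1, self.n_populations + 1, dtype=float)
            self.mixture_weights = tuple(w / w.sum())
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ParameterError("mixture weights must sum to 1")
        if not set(self.informative) <= set(range(self.n_markers)):
            raise ParameterError("informative markers outside 0..p-1")
        if self.effect < 0:
            raise ParameterError("effect must be >= 0")
        if self.cells_range[0] < 1 or self.cells_range[0] > self.cells_range[1]:
            raise ParameterError("cells_range must satisfy 1 <= lo <= hi")


@dataclass
class GroundTruth:
    outcomes: dict[str, int]
    informative: tuple[int, ...]
    effect: float
    batch_of_subject: dict[str, int]
    populations: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)


def _population_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """K x p component means; spread out so populations are distinct."""
    return rng.normal(0.0, 1.5, size=(cfg.n_populations, cfg.n_markers))


def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from the configured mixture law.

    Class-1 subjects have all population means shifted by ``+effect`` on the
    informative markers (at the configured timepoints).  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    means = _population_means(cfg, rng)
    markers = [f"M{j}" for j in range(cfg.n_markers)]
    shift_tp = (
        set(cfg.shift_timepoints)
        if cfg.shift_timepoints is not None
        else set(range(1, cfg.n_timepoints + 1))
    )
    batch_offsets = rng.normal(0.0, 1.0, size=(cfg.n_batches, cfg.n_markers)) * cfg.batch_shift

    subjects = [f"S{n:03d}" for n in range(cfg.n_subjects)]
    if cfg.n_classes == 2:
        y = (rng.random(cfg.n_subjects) < cfg.class_balance).astype(int)
        # guarantee both classes occur so the cohort is usable for CV
        if y.min() == y.max():
            y[0] = 1 - y[0]
    else:
        y = rng.integers(0, cfg.n_classes, size=cfg.n_subjects)
        for c in range(cfg.n_classes):
            if not (y == c).any():
                y[c] = c
    batches = rng.integers(0, cfg.n_batches, size=cfg.n_subjects)

    samples: dict[tuple[str, int], CellMatrix] = {}
    truth = GroundTruth(
        outcomes=dict(zip(subjects, (int(v) for v in y))),
        informative=tuple(cfg.informative),
        effect=cfg.effect,
        batch_of_subject=dict(zip(subjects, (int(b) for b in batches))),
    )
    weights = np.asarray(cfg.mixture_weights)
    for n, sid in enumerate(subjects):
        for t in range(1, cfg.n_timepoints + 1):
            if cfg.missing_prob > 0 and rng.random() < cfg.missing_prob:
                continue
            m = int(rng.integers(cfg.cells_range[0], cfg.cells_range[1] + 1))
            pops = rng.choice(cfg.n_populations, size=m, p=weights)
            X = means[pops] + rng.normal(0.0, cfg.population_spread, size=(m, cfg.n_markers))
            if y[n] >= 1 and t in shift_tp:
                # class shift scales with class index in the multiclass case
                X[:, list(cfg.informative)] += cfg.effect * y[n]
            X += batch_offsets[batches[n]]
            samples[(sid, t)] = CellMatrix(X, markers, sid, t)
            truth.populations[(sid, t)] = pops
    # never lose a subject entirely to missingness: restore visit 1 if needed
    for n, sid in enumerate(subjects):
        if not any((sid, t) in samples for t in range(1, cfg.n_timepoints + 1)):
            m = int(rng.integers(cfg.cells_range[0], cfg.cells_range[1] + 1))
            pops = rng.choice(cfg.n_populations, size=m, p=weights)
            X = means[pops] + rng.normal(0.0, cfg.population_spread, size=(m, cfg.n_markers))
            if y[n] >= 1 and 1 in shift_tp:
                X[:, list(cfg.informative)] += cfg.effect * y[n]
            X += batch_offsets[batches[n]]
            samples[(sid, 1)] = CellMatrix(X, markers, sid, 1)
            truth.populations[(sid, 1)] = pops

    cohort = Cohort(
        samples=samples,
        outcomes=truth.outcomes,
        n_timepoints=cfg.n_timepoints,
        marker_names=markers,
    )
    return cohort, truth


def simulate_counts(
    cfg: SimConfig, depth: int, seed: int | None = None, n_cells: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson gene-count matrix exercising the scRNA-seq preprocessing path.

    Per-gene base rates are lognormal; each cell's library size varies
    lognormally around ``depth``.  Cells of class 1 have their rates on the
    informative genes multiplied by ``exp(effect)``.  Returns (counts,
    per-cell class labels); ``depth=0`` yields an all-zero matrix.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_cells = n_cells or 200
    base = rng.lognormal(0.0, 1.0, size=cfg.n_markers)
    y = (rng.random(n_cells) < cfg.class_balance).astype(int)
    scale = rng.lognormal(0.0, 0.3, size=n_cells)
    rates = np.tile(base, (n_cells, 1))
    rates[y == 1][:, :]  # no-op guard for empty class
    rates[np.ix_(y == 1, list(cfg.informative))] *= np.exp(cfg.effect)
    rates /= rates.sum(axis=1, keepdims=True)
    lam = rates * (scale * depth)[:, None]
    return rng.poisson(lam).astype(np.int64), y
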