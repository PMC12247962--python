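"""Cohort data model for longitudinal single-cell cytometry.

A *sample* is the set of cells measured for one subject at one visit,
stored as a cells x markers matrix.  Cell counts are ragged: they may
differ across subjects and timepoints.  A :class:`Cohort` collects the
samples of a study together with per-subject outcomes and optional
subject-level covariates; missing visits are recorded explicitly in a
missingness registry rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A delimited sample table violates the expected format."""


class SchemaError(ValueError):
    """Marker names/order differ across samples of one cohort."""


class LabelError(ValueError):
    """A sampled subject has no outcome label."""


class ParameterError(ValueError):
    """An argument is outside its valid range."""


@dataclass
class CellMatrix:
    """One (subject, timepoint) sample: ``values`` is cells x markers."""

    values: np.ndarray
    marker_names: list[str]
    subject_id: str
    timepoint: int

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.marker_names))
        if self.values.shape[1] != len(self.marker_names):
            raise SchemaError(
                f"sample ({self.subject_id}, t={self.timepoint}): "
                f"{self.values.shape[1]} columns but {len(self.marker_names)} marker names"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at cell {i}, marker {self.marker_names[j]!r} "
                f"in sample ({self.subject_id}, t={self.timepoint})"
            )
        self.timepoint = int(self.timepoint)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class Cohort:
    """All samples of a study, keyed by (subject_id, timepoint)."""

    samples: dict[tuple[str, int], CellMatrix]
    outcomes: dict[str, int]
    n_timepoints: int
    covariates: dict[str, np.ndarray] | None = None
    marker_names: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.outcomes)

    @property
    def n_subjects(self) -> int:
        return len(self.outcomes)

    @property
    def total_cells(self) -> int:
        return sum(s.n_cells for s in self.samples.values())

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def missing(self) -> set[tuple[str, int]]:
        """Registry of absent (subject, timepoint) visits."""
        return {
            (sid, t)
            for sid in self.subjects
            for t in range(1, self.n_timepoints + 1)
            if (sid, t) not in self.samples
        }

    @property
    def n_classes(self) -> int:
        return int(max(self.outcomes.values())) + 1

    def outcome_vector(self) -> np.ndarray:
        return np.array([self.outcomes[s] for s in self.subjects], dtype=int)

    def subject_samples(self, sid: str) -> dict[int, CellMatrix]:
        return {
            t: self.samples[(sid, t)]
            for t in range(1, self.n_timepoints + 1)
            if (sid, t) in self.samples
        }

    def subset_subjects(self, keep: list[str]) -> "Cohort":
        keep = set(keep)
        return Cohort(
            samples={k: v for k, v in self.samples.items() if k[0] in keep},
            outcomes={s: y for s, y in self.outcomes.items() if s in keep},
            n_timepoints=self.n_timepoints,
            covariates=(
                {s: c for s, c in self.covariates.items() if s in keep}
                if self.covariates
                else None
            ),
            marker_names=list(self.marker_names),
        )

    def all_cells(self) -> np.ndarray:
        """Concatenation of every sample's cells (M x p), subjects sorted."""
        mats = [
            self.samples[(sid, t)].values
            for sid in self.subjects
            for t in range(1, self.n_timepoints + 1)
            if (sid, t) in self.samples
        ]
        if not mats:
            return np.empty((0, self.n_markers))
        return np.vstack(mats)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_sample_table(path, subject_id: str, timepoint: int) -> CellMatrix:
    """Read one delimited (CSV/TSV) cells x markers table.

    The first row must be a header of marker names; every following row is
    one cell.  Non-numeric or missing entries raise :class:`FormatError`
    naming the offending row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file")
        delim = _detect_delimiter(header_line)
        names = [c.strip() for c in header_line.strip().split(delim)]
        if all(_is_number(c) for c in names):
            raise FormatError(
                f"{path}: first row looks numeric; a header of marker names is required"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.strip().split(delim)
            if len(fields) != len(names):
                raise FormatError(
                    f"{path}: row {lineno} has {len(fields)} columns, "
                    f"expected {len(names)}"
                )
            rows.append(fields)
    if not rows:
        return CellMatrix(np.empty((0, len(names))), names, subject_id, timepoint)
    raw = np.array(rows, dtype=object)
    try:
        # str -> float64 goes through exact per-element parsing (round-trip safe)
        values = raw.astype(np.float64)
    except (ValueError, TypeError):
        for i, row in enumerate(rows):
            for j, field in enumerate(row):
                if not _is_number(field):
                    raise FormatError(
                        f"{path}: non-numeric value {field!r} at row {i + 2}, "
                        f"column {names[j]!r}"
                    ) from None
        raise
    return CellMatrix(values, names, subject_id, timepoint)


def write_sample_table(cm: CellMatrix, path) -> None:
    """Write a sample back to CSV; round-trips finite values bit-exactly."""
    df = pd.DataFrame(cm.values, columns=cm.marker_names)
    df.to_csv(path, index=False, float_format="%.17g")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def assemble_cohort(
    samples: list[CellMatrix],
    outcomes: dict[str, int],
    covariates: dict[str, np.ndarray] | None = None,
    n_timepoints: int | None = None,
) -> Cohort:
    """Build a Cohort, checking marker-schema and label consistency."""
    if not samples:
        raise ParameterError("no samples provided")
    ref = samples[0].marker_names
    keyed: dict[tuple[str, int], CellMatrix] = {}
    for s in samples:
        if s.marker_names != ref:
            raise SchemaError(
                f"sample ({s.subject_id}, t={s.timepoint}) marker names differ "
                f"from the cohort schema: {s.marker_names} vs {ref}"
            )
        key = (s.subject_id, s.timepoint)
        if key in keyed:
            raise ParameterError(f"duplicate sample for {key}")
        keyed[key] = s
        if s.subject_id not in outcomes:
            raise LabelError(f"subject {s.subject_id!r} has no outcome label")
    labels = set(int(v) for v in outcomes.values())
    if not labels <= set(range(max(labels) + 1)):
        raise LabelError(f"outcomes must be class indices 0..C-1, got {sorted(labels)}")
    T = n_timepoints or max(t for _, t in keyed)
    if covariates is not None:
        covariates = {s: np.asarray(c, dtype=np.float64) for s, c in covariates.items()}
    return Cohort(
        samples=keyed,
        outcomes={s: int(v) for s, v in outcomes.items()},
        n_timepoints=T,
        covariates=covariates,
        marker_names=list(ref),
    )


def read_manifest(path) -> Cohort:
    """Load a cohort from a YAML/JSON manifest.

    Schema::

        n_timepoints: 2            # optional
        samples:
          - {subject: A, timepoint: 1, path: A_t1.csv}
        outcomes: {A: 1, B: 0}
        covariates: {A: [1, 0], B: [0, 1]}   # optional

    Relative sample paths resolve against the manifest's directory.
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
    samples = [
        load_sample_table(
            path.parent / entry["path"], str(entry["subject"]), int(entry["timepoint"])
        )
        for entry in manifest["samples"]
    ]
    covs = manifest.get("covariates")
    if covs is not None:
        covs = {str(k): np.asarray(v, dtype=float) for k, v in covs.items()}
    return assemble_cohort(
        samples,
        {str(k): int(v) for k, v in manifest["outcomes"].items()},
        covariates=covs,
        n_timepoints=manifest.get("n_timepoints"),
    )


# ---------------------------------------------------------------------------
# Robustness-protocol transforms
# ---------------------------------------------------------------------------

def subsample_cells(cohort: Cohort, fraction: float, seed: int) -> Cohort:
    """Independently retain ``ceil(fraction * m)`` cells per sample.

    Cells are drawn uniformly without replacement; the ceiling guarantees a
    nonempty sample stays nonempty for any fraction > 0.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    new = {}
    for key in sorted(cohort.samples):
        cm = cohort.samples[key]
        m = cm.n_cells
        k = int(np.ceil(fraction * m))
        idx = np.sort(rng.choice(m, size=k, replace=False)) if m else np.arange(0)
        new[key] = CellMatrix(cm.values[idx], cm.marker_names, cm.subject_id, cm.timepoint)
    return Cohort(
        samples=new,
        outcomes=dict(cohort.outcomes),
        n_timepoints=cohort.n_timepoints,
        covariates=cohort.covariates,
        marker_names=list(cohort.marker_names),
    )


def mask_timepoint(cohort: Cohort, timepoint: int, fraction: float, seed: int) -> Cohort:
    """Remove one visit for a random fraction of subjects.

    Emulates missed follow-up visits: the chosen subjects lose their sample
    at ``timepoint``, which then appears in the missingness registry.
    """
    if not 1 <= timepoint <= cohort.n_timepoints:
        raise ParameterError(f"timepoint {timepoint} outside 1..{cohort.n_timepoints}")
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    subjects = cohort.subjects
    n_drop = int(round(fraction * len(subjects)))
    drop = set(rng.choice(subjects, size=n_drop, replace=False)) if n_drop else set()
    new = {
        k: v
        for k, v in cohort.samples.items()
        if not (k[0] in drop and k[1] == timepoint)
    }
    return Cohort(
        samples=new,
        outcomes=dict(cohort.outcomes),
        n_timepoints=cohort.n_timepoints,
        covariates=cohort.covariates,
        marker_names=list(cohort.marker_names),
    )
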