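"""Cohort data model: I/O, assembly, missingness, robustness transforms."""

import numpy as np
import pytest

from cytogpnet.data import (
    CellMatrix,
    FormatError,
    LabelError,
    ParameterError,
    SchemaError,
    assemble_cohort,
    load_sample_table,
    mask_timepoint,
    read_manifest,
    subsample_cells,
    write_sample_table,
)


@pytest.fixture
def two_subject_cohort():
    rng = np.random.default_rng(0)
    markers = ["CD8", "KLRG1", "CD4"]
    samples = [
        CellMatrix(rng.normal(size=(10, 3)), markers, sid, t)
        for sid in ("A", "B")
        for t in (1, 2)
    ]
    return assemble_cohort(samples, {"A": 1, "B": 0})


def test_load_sample_table_shapes_and_delimiters(tmp_path):
    f = tmp_path / "s.csv"
    f.write_text("CD8,KLRG1\n1.0,2.0\n3.5,4.25\n-1.0,0.0\n")
    cm = load_sample_table(f, "A", 1)
    assert cm.marker_names == ["CD8", "KLRG1"]
    assert cm.values.shape == (3, 2)
    assert cm.n_cells == 3 and cm.n_markers == 2
    # TSV autodetected from the header line
    g = tmp_path / "s.tsv"
    g.write_text("CD8\tKLRG1\n1.0\t2.0\n")
    assert load_sample_table(g, "A", 1).values.shape == (1, 2)


def test_load_sample_table_header_only_gives_empty_sample(tmp_path):
    f = tmp_path / "empty.csv"
    f.write_text("CD8,KLRG1\n")
    cm = load_sample_table(f, "A", 1)
    assert cm.n_cells == 0 and cm.n_markers == 2


@pytest.mark.parametrize(
    "content,match",
    [
        ("CD8,KLRG1\n1.0,NA\n", "NA"),
        ("CD8,KLRG1\nx,2.0\n", "'x'"),
        ("1.0,2.0\n3.0,4.0\n", "header"),
        ("CD8,KLRG1\n1.0,2.0,3.0\n", "column"),
    ],
)
def test_load_sample_table_format_errors(tmp_path, content, match):
    f = tmp_path / "bad.csv"
    f.write_text(content)
    with pytest.raises(FormatError, match=match):
        load_sample_table(f, "A", 1)


def test_write_read_round_trip_bit_exact(tmp_path):
    rng = np.random.default_rng(3)
    cm = CellMatrix(rng.normal(size=(20, 4)) * 1e3, ["a", "b", "c", "d"], "S", 1)
    f = tmp_path / "rt.csv"
    write_sample_table(cm, f)
    back = load_sample_table(f, "S", 1)
    np.testing.assert_array_equal(back.values, cm.values)


def test_assemble_cohort_counts(two_subject_cohort):
    c = two_subject_cohort
    assert c.n_subjects == 2
    assert c.n_timepoints == 2
    assert c.total_cells == 40
    assert c.missing == set()
    assert c.outcome_vector().tolist() == [1, 0]


def test_assemble_cohort_order_insensitive():
    rng = np.random.default_rng(1)
    samples = [
        CellMatrix(rng.normal(size=(5, 2)), ["x", "y"], sid, t)
        for sid in ("A", "B")
        for t in (1, 2)
    ]
    a = assemble_cohort(samples, {"A": 0, "B": 1})
    b = assemble_cohort(samples[::-1], {"A": 0, "B": 1})
    assert set(a.samples) == set(b.samples)
    for k in a.samples:
        np.testing.assert_array_equal(a.samples[k].values, b.samples[k].values)


def test_missing_visit_registered_not_dropped():
    rng = np.random.default_rng(2)
    samples = [
        CellMatrix(rng.normal(size=(5, 2)), ["x", "y"], "A", 1),
        CellMatrix(rng.normal(size=(5, 2)), ["x", "y"], "A", 2),
        CellMatrix(rng.normal(size=(5, 2)), ["x", "y"], "B", 1),
    ]
    c = assemble_cohort(samples, {"A": 0, "B": 1}, n_timepoints=2)
    assert c.missing == {("B", 2)}


def test_assemble_cohort_error_contracts():
    rng = np.random.default_rng(4)
    a = CellMatrix(rng.normal(size=(3, 2)), ["x", "y"], "A", 1)
    b_reordered = CellMatrix(rng.normal(size=(3, 2)), ["y", "x"], "B", 1)
    with pytest.raises(SchemaError):
        assemble_cohort([a, b_reordered], {"A": 0, "B": 1})
    with pytest.raises(LabelError):
        assemble_cohort([a], {})


def test_subsample_cells_counts_and_determinism(two_subject_cohort):
    c = two_subject_cohort
    same = subsample_cells(c, 1.0, seed=0)
    for k in c.samples:
        np.testing.assert_array_equal(same.samples[k].values, c.samples[k].values)
    half = subsample_cells(c, 0.5, seed=0)
    assert all(s.n_cells == 5 for s in half.samples.values())
    again = subsample_cells(c, 0.5, seed=0)
    for k in c.samples:
        np.testing.assert_array_equal(half.samples[k].values, again.samples[k].values)
    with pytest.raises(ParameterError):
        subsample_cells(c, 0.0, seed=0)


def test_subsample_cells_subset_no_duplicates(two_subject_cohort):
    sub = subsample_cells(two_subject_cohort, 0.7, seed=5)
    for k, cm in sub.samples.items():
        orig = two_subject_cohort.samples[k].values
        # every retained row appears in the original exactly once
        seen = set()
        for row in cm.values:
            matches = np.flatnonzero((orig == row).all(axis=1))
            assert len(matches) >= 1
            assert matches[0] not in seen
            seen.add(matches[0])


def test_subsample_ceiling_keeps_nonempty():
    cm = CellMatrix(np.ones((3, 2)), ["x", "y"], "A", 1)
    c = assemble_cohort([cm], {"A": 0}, n_timepoints=1)
    out = subsample_cells(c, 0.01, seed=0)
    assert out.samples[("A", 1)].n_cells == 1


def test_mask_timepoint_fractions():
    rng = np.random.default_rng(6)
    samples = [
        CellMatrix(rng.normal(size=(4, 2)), ["x", "y"], f"S{i}", t)
        for i in range(20)
        for t in (1, 2)
    ]
    c = assemble_cohort(samples, {f"S{i}": i % 2 for i in range(20)})
    assert mask_timepoint(c, 2, 0.0, seed=0).missing == set()
    masked = mask_timepoint(c, 2, 0.1, seed=0)
    assert len(masked.missing) == 2
    assert all(t == 2 for _, t in masked.missing)
    allgone = mask_timepoint(c, 2, 1.0, seed=0)
    assert len(allgone.missing) == 20


def test_manifest_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    for sid in ("A", "B"):
        for t in (1, 2):
            write_sample_table(
                CellMatrix(rng.normal(size=(6, 2)), ["x", "y"], sid, t),
                tmp_path / f"{sid}_{t}.csv",
            )
    manifest = tmp_path / "cohort.yaml"
    manifest.write_text(
        "n_timepoints: 2\n"
        "samples:\n"
        + "".join(
            f"  - {{subject: {sid}, timepoint: {t}, path: {sid}_{t}.csv}}\n"
            for sid in ("A", "B")
            for t in (1, 2)
        )
        + "outcomes: {A: 1, B: 0}\n"
        + "covariates: {A: [1.0, 0.0], B: [0.0, 1.0]}\n"
    )
    c = read_manifest(manifest)
    assert c.n_subjects == 2 and c.total_cells == 24
    assert c.covariates["A"].tolist() == [1.0, 0.0]
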