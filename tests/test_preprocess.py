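"""Replicate averaging, normalization, filtering and unit projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from timepatterns.io import ExpressionMatrix, SampleKey, ValidationError
from timepatterns.preprocess import (
    GeneAnnotationTable,
    average_replicates,
    filter_protein_coding,
    flatten_to_unit_profiles,
    normalize,
    quantile_normalize,
    read_annotation_table,
    to_tensor,
)

from conftest import make_matrix, write_tsv


def test_average_replicates_published_triplet():
    # three replicate intensities of one gene at one (condition, timepoint)
    keys = [SampleKey("intactmale", "day0", f"rep{i}") for i in (1, 2, 3)]
    m = ExpressionMatrix(["NM_013477"], keys, np.array([[1281.1, 1158.5, 1455.8]]),
                         "microarray")
    avg = average_replicates(m)
    assert avg.values.shape == (1, 1)
    assert avg.values[0, 0] == pytest.approx(1298.4667, abs=1e-4)
    assert not avg.sample_keys[0].has_replicate


def test_average_replicates_single_replicate_identity():
    m = make_matrix(replicates=("r1",))
    avg = average_replicates(m)
    np.testing.assert_array_equal(avg.values, m.values)


def test_average_replicates_invariant_to_replicate_order():
    m = make_matrix(seed=5)
    perm = np.random.default_rng(0).permutation(len(m.sample_keys))
    shuffled = ExpressionMatrix(m.gene_ids, [m.sample_keys[i] for i in perm],
                                m.values[:, perm], m.data_type)
    a, b = average_replicates(m), average_replicates(shuffled)
    lookup = {k: j for j, k in enumerate(b.sample_keys)}
    reordered = b.values[:, [lookup[k] for k in a.sample_keys]]
    np.testing.assert_allclose(a.values, reordered)


def test_quantile_normalization_worked_example():
    values = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
    out = quantile_normalize(values)
    np.testing.assert_allclose(out, np.array([[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]]))


def test_quantile_normalization_fixed_point_and_common_distribution():
    rng = np.random.default_rng(1)
    values = rng.gamma(2.0, 5.0, size=(50, 4))
    out = quantile_normalize(values)
    # all columns share the same sorted value vector afterwards
    sorted_cols = np.sort(out, axis=0)
    for j in range(1, 4):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
    # identical columns are a fixed point
    same = np.tile(values[:, :1], (1, 3))
    np.testing.assert_allclose(quantile_normalize(same), same)


def test_normalize_disabled_is_identity(small_matrix):
    assert normalize(small_matrix, enabled=False) is small_matrix


def test_normalize_rnaseq_log_scales_before_quantile():
    m = make_matrix(n_genes=30, seed=7)
    out = normalize(m, enabled=True)
    assert out.values.max() < m.values.max()  # log2 compression happened
    sorted_cols = np.sort(out.values, axis=0)
    for j in range(1, out.values.shape[1]):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])


def test_filter_protein_coding_counts(tmp_path):
    m = make_matrix(5)
    path = write_tsv(
        tmp_path / "ann.tsv",
        ["gene_id", "canonical_id", "symbol", "biotype"],
        [
            ["g0", "ENSG0", "S0", "protein_coding"],
            ["g1", "ENSG1", "S1", "protein_coding"],
            ["g2", "ENSG2", "S2", "protein_coding"],
            ["g3", "ENSG3", "S3", "lncRNA"],
        ],
    )
    ann = read_annotation_table(path)
    out, report = filter_protein_coding(m, ann, enabled=True)
    assert out.gene_ids == ["g0", "g1", "g2"]
    assert report == {"enabled": True, "kept": 3,
                      "dropped_unannotated": 1, "dropped_noncoding": 1}


def test_filter_protein_coding_disabled_and_errors(small_matrix):
    out, report = filter_protein_coding(small_matrix, None, enabled=False)
    assert out is small_matrix and report["kept"] == 4
    with pytest.raises(ValidationError):
        filter_protein_coding(small_matrix, None, enabled=True)
    with pytest.raises(ValidationError, match="empty analysis set"):
        filter_protein_coding(small_matrix, GeneAnnotationTable({}), enabled=True)


def test_to_tensor_label_lookup():
    m = make_matrix(2, conditions=("A", "B"), timepoints=("t1", "t2", "t3"),
                    replicates=None, seed=9)
    t = to_tensor(m)
    assert t.values.shape == (2, 2, 3)
    col = {(k.condition, k.timepoint): j for j, k in enumerate(m.sample_keys)}
    for ci, c in enumerate(t.conditions):
        for ti, tp in enumerate(t.timepoints):
            np.testing.assert_array_equal(t.values[:, ci, ti], m.values[:, col[(c, tp)]])


def test_to_tensor_missing_combination_rejected():
    keys = [SampleKey("A", "t1"), SampleKey("A", "t2"), SampleKey("B", "t1")]
    m = ExpressionMatrix(["g1"], keys, np.ones((1, 3)))
    with pytest.raises(ValidationError, match="B_t2"):
        to_tensor(m)


def test_flatten_345_triangle():
    m = make_matrix(1, conditions=("A", "B"), timepoints=("t1", "t2"), replicates=None,
                    values=np.array([[3.0, 0.0, 4.0, 0.0]]))
    # condition-major layout: A_t1, A_t2, B_t1, B_t2 -> (3, 0, 4, 0)
    profiles, dropped = flatten_to_unit_profiles(to_tensor(m))
    np.testing.assert_allclose(profiles.vectors, [[0.6, 0.0, 0.8, 0.0]])
    assert dropped == []


def test_flatten_drops_zero_genes_and_reports():
    m = make_matrix(2, conditions=("A", "B"), timepoints=("t1", "t2"), replicates=None,
                    values=np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]]))
    profiles, dropped = flatten_to_unit_profiles(to_tensor(m))
    assert dropped == ["g0"]
    assert profiles.gene_ids == ["g1"]
    np.testing.assert_allclose(np.linalg.norm(profiles.vectors, axis=1), 1.0, atol=1e-9)


@settings(deadline=None, max_examples=25)
@given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
def test_unit_profiles_scale_invariant(scale, seed):
    rng = np.random.default_rng(seed)
    values = rng.gamma(2.0, 10.0, size=(3, 8))
    m1 = make_matrix(3, conditions=("A", "B"), timepoints=("t1", "t2", "t3", "t4"),
                     replicates=None, values=values)
    m2 = make_matrix(3, conditions=("A", "B"), timepoints=("t1", "t2", "t3", "t4"),
                     replicates=None, values=values * scale)
    p1, _ = flatten_to_unit_profiles(to_tensor(m1))
    p2, _ = flatten_to_unit_profiles(to_tensor(m2))
    np.testing.assert_allclose(p1.vectors, p2.vectors, atol=1e-9)
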