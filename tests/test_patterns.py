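"""Discretization, NMI/agreement statistics, permutation test and pattern calls."""

import itertools

import numpy as np
import pytest

from timepatterns.clustering import ClusterResult, spherical_kmeans
from timepatterns.patterns import (
    PairwiseSimilarity,
    agreement_score,
    call_patterns,
    classify_cluster,
    discretize_cluster,
    pairwise_nmi,
    permutation_p,
)
from timepatterns.preprocess import (
    TimeCourseTensor,
    average_replicates,
    flatten_to_unit_profiles,
    to_tensor,
)
from timepatterns.simulate import ClusterSpec, canonical_fixture_spec, generate


def tensor_from_rows(rows_by_condition):
    """Build a (G, C, T) tensor from per-condition lists of per-gene time courses."""
    values = np.array(rows_by_condition, dtype=float).transpose(1, 0, 2)
    n_genes, n_cond, n_t = values.shape
    return TimeCourseTensor(
        [f"g{i}" for i in range(n_genes)],
        [f"c{i + 1}" for i in range(n_cond)],
        [f"t{i + 1}" for i in range(n_t)],
        values,
    )


@pytest.mark.parametrize(
    "series, expected",
    [
        ((1.0, 5.0, 9.0), (0, 1, 2)),
        ((4.0, 4.0, 4.0), (0, 0, 0)),  # ties share the lower level
        ((9.0, 1.0, 5.0), (2, 0, 1)),
    ],
)
def test_discretize_single_series(series, expected):
    t = tensor_from_rows([[series], [series]])
    levels = discretize_cluster(t, ["g0"], bins=3)
    assert tuple(levels[0, 0]) == expected


def test_discretize_rejects_more_bins_than_timepoints():
    t = tensor_from_rows([[(1.0, 2.0, 3.0)], [(1.0, 2.0, 3.0)]])
    with pytest.raises(ValueError, match="bins"):
        discretize_cluster(t, ["g0"], bins=4)


def plugin_nmi_oracle(a, b):
    """Independent plug-in NMI from raw counts (direct formula)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    mi = h_a = h_b = 0.0
    for x in np.unique(a):
        px = np.mean(a == x)
        h_a -= px * np.log(px)
    for y in np.unique(b):
        py = np.mean(b == y)
        h_b -= py * np.log(py)
    for x in np.unique(a):
        for y in np.unique(b):
            pxy = np.mean((a == x) & (b == y))
            if pxy > 0:
                mi += pxy * np.log(pxy / (np.mean(a == x) * np.mean(b == y)))
    return mi / ((h_a + h_b) / 2)


def levels_array(a, b):
    return np.stack([np.asarray(a)[None, :], np.asarray(b)[None, :]], axis=1)


def test_nmi_identical_sequences_is_one():
    lv = levels_array([0, 0, 1, 1], [0, 0, 1, 1])
    assert pairwise_nmi(lv, 0, 1) == pytest.approx(1.0)


def test_nmi_independent_by_construction_is_zero():
    lv = levels_array([0, 1, 0, 1], [0, 0, 1, 1])
    assert pairwise_nmi(lv, 0, 1) == pytest.approx(0.0, abs=1e-12)


def test_nmi_matches_plugin_oracle_on_2x2_joint():
    # joint counts [[2, 1], [1, 2]]
    a = [0, 0, 0, 1, 1, 1]
    b = [0, 0, 1, 0, 1, 1]
    lv = levels_array(a, b)
    assert pairwise_nmi(lv, 0, 1) == pytest.approx(plugin_nmi_oracle(a, b), abs=1e-12)


def test_nmi_degenerate_marginals():
    assert pairwise_nmi(levels_array([0, 0, 0], [0, 0, 0]), 0, 1) == 1.0
    assert pairwise_nmi(levels_array([0, 0, 0], [0, 1, 2]), 0, 1) == 0.0


def test_agreement_score_counts_matches():
    lv = levels_array([0, 1, 2, 0], [0, 2, 2, 1])
    assert agreement_score(lv, 0, 1) == pytest.approx(0.5)


def test_permutation_p_identical_patterns_significant():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(50, 6))
    t = tensor_from_rows([base, base])
    levels = discretize_cluster(t, t.gene_ids)
    for stat in ("agreement", "nmi"):
        p = permutation_p(levels, 0, 1, n_perm=999, rng_seed=1, statistic=stat)
        assert p <= 0.01


def test_permutation_p_bounds_and_determinism():
    rng = np.random.default_rng(1)
    t = tensor_from_rows([rng.normal(size=(10, 6)), rng.normal(size=(10, 6))])
    levels = discretize_cluster(t, t.gene_ids)
    p1 = permutation_p(levels, 0, 1, n_perm=199, rng_seed=7)
    p2 = permutation_p(levels, 0, 1, n_perm=199, rng_seed=7)
    assert p1 == p2
    assert p1 >= 1.0 / 200.0
    with pytest.raises(ValueError):
        permutation_p(levels, 0, 1, n_perm=50)


def test_permutation_p_null_roughly_uniform():
    rng = np.random.default_rng(2)
    high = 0
    for i in range(40):
        t = tensor_from_rows([rng.normal(size=(15, 6)), rng.normal(size=(15, 6))])
        levels = discretize_cluster(t, t.gene_ids)
        p = permutation_p(levels, 0, 1, n_perm=199, rng_seed=i)
        high += p > 0.05
    assert high >= 36  # >= 90% of independent null pairs are non-significant


def test_permutation_p_invariant_to_gene_order():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=(12, 6)), rng.normal(size=(12, 6))
    t1 = tensor_from_rows([a, b])
    levels1 = discretize_cluster(t1, t1.gene_ids)
    perm = rng.permutation(12)
    t2 = tensor_from_rows([a[perm], b[perm]])
    keys1 = t1.gene_ids
    keys2 = [t1.gene_ids[i] for i in perm]  # ids travel with their rows
    levels2 = discretize_cluster(t2, t2.gene_ids)
    p1 = permutation_p(levels1, 0, 1, n_perm=199, rng_seed=5, gene_keys=keys1)
    p2 = permutation_p(levels2, 0, 1, n_perm=199, rng_seed=5, gene_keys=keys2)
    assert p1 == p2


def _pair(a, b, verdict):
    return PairwiseSimilarity(a, b, 0.5, 0.5, 0.01 if verdict == "similar" else 0.9, verdict)


def test_classify_cluster_exhaustive_three_conditions():
    """All 2^3 verdict patterns for C=3: 0 different pairs -> SEP, 3 -> DEP,
    2 sharing a condition -> ODEP of that condition, 1 -> mixed."""
    conds = ["c1", "c2", "c3"]
    pairs = list(itertools.combinations(conds, 2))
    for verdict_bits in itertools.product(["similar", "different"], repeat=3):
        pw = [_pair(a, b, v) for (a, b), v in zip(pairs, verdict_bits)]
        label, odep = classify_cluster(pw, conds)
        n_diff = verdict_bits.count("different")
        if n_diff == 0:
            assert (label, odep) == ("SEP", None)
        elif n_diff == 3:
            assert (label, odep) == ("DEP", None)
        elif n_diff == 2:
            assert label == "ODEP"
            diff_pairs = [p for p, v in zip(pairs, verdict_bits) if v == "different"]
            (common,) = set(diff_pairs[0]) & set(diff_pairs[1])
            assert odep == common
        else:
            assert (label, odep) == ("mixed", None)


def test_classify_cluster_spec_case_c3():
    conds = ["c1", "c2", "c3"]
    pw = [_pair("c1", "c2", "similar"), _pair("c1", "c3", "different"),
          _pair("c2", "c3", "different")]
    assert classify_cluster(pw, conds) == ("ODEP", "c3")


def test_classify_cluster_c4_disjoint_similar_pairs_is_mixed():
    conds = ["c1", "c2", "c3", "c4"]
    similar = {("c1", "c2"), ("c3", "c4")}
    pw = [
        _pair(a, b, "similar" if (a, b) in similar else "different")
        for a, b in itertools.combinations(conds, 2)
    ]
    assert classify_cluster(pw, conds) == ("mixed", None)


def _truth_cluster_result(profiles, truth_ids):
    """ClusterResult built from ground-truth assignments (centroid = normalized mean)."""
    ids = sorted(set(truth_ids))
    remap = {c: i for i, c in enumerate(ids)}
    assignments = np.array([remap[c] for c in truth_ids])
    centroids = np.vstack([
        profiles.vectors[assignments == i].sum(axis=0) for i in range(len(ids))
    ])
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    return ClusterResult(assignments, centroids, 0.0, 0.0, 1, 0)


def planted_calls(noise_sd=0.0, seed=0, **kwargs):
    ds = generate(canonical_fixture_spec(noise_sd=noise_sd, rng_seed=seed))
    tensor = to_tensor(average_replicates(ds.matrix))
    profiles, _ = flatten_to_unit_profiles(tensor)
    truth = dict(zip(ds.truth.gene_id, ds.truth.cluster_id))
    result = _truth_cluster_result(profiles, [truth[g] for g in profiles.gene_ids])
    calls = call_patterns(tensor, result, rng_seed=seed + 1,
                          profile_gene_ids=profiles.gene_ids, **kwargs)
    return ds, calls


def test_zero_noise_fixture_labels_exactly_recovered():
    ds, calls = planted_calls(noise_sd=0.0, seed=0)
    expected = [(c.pattern_type, c.odep_condition) for c in ds.spec.clusters]
    got = [(c.label, c.odep_condition) for c in calls]
    assert got == expected
    assert all(c.significant for c in calls)


def test_small_cluster_excluded_as_mixed():
    ds, calls = planted_calls(noise_sd=0.0, seed=0, min_cluster_size=41)
    assert all(c.label == "mixed" and not c.significant for c in calls)


def test_flat_cluster_called_sep_by_convention():
    t = tensor_from_rows([np.full((6, 6), 3.0), np.full((6, 6), 3.0)])
    result = _truth_cluster_result(
        type("P", (), {"vectors": np.full((6, 4), 0.5)})(), [0] * 6
    )
    calls = call_patterns(t, result, rng_seed=0, profile_gene_ids=t.gene_ids)
    assert calls[0].label == "SEP"


def test_labels_invariant_to_gene_order():
    ds, calls1 = planted_calls(noise_sd=0.05, seed=4)
    # shuffle genes (rows of the tensor) and redo
    spec = canonical_fixture_spec(noise_sd=0.05, rng_seed=4)
    ds2 = generate(spec)
    tensor = to_tensor(average_replicates(ds2.matrix))
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(tensor.gene_ids))
    shuffled = TimeCourseTensor(
        [tensor.gene_ids[i] for i in perm], tensor.conditions, tensor.timepoints,
        tensor.values[perm],
    )
    profiles, _ = flatten_to_unit_profiles(shuffled)
    truth = dict(zip(ds2.truth.gene_id, ds2.truth.cluster_id))
    result = _truth_cluster_result(profiles, [truth[g] for g in profiles.gene_ids])
    calls2 = call_patterns(shuffled, result, rng_seed=5, profile_gene_ids=profiles.gene_ids)
    assert [(c.label, c.odep_condition) for c in calls1] == \
        [(c.label, c.odep_condition) for c in calls2]


def test_similar_verdicts_monotone_in_alpha():
    ds, strict = planted_calls(noise_sd=0.05, seed=2, alpha=0.002)
    _, loose = planted_calls(noise_sd=0.05, seed=2, alpha=0.3)
    for cs, cl in zip(strict, loose):
        for ps, pl in zip(cs.pairwise, cl.pairwise):
            if ps.verdict == "similar":
                assert pl.verdict == "similar"


def test_cluster_p_and_q_ranges():
    _, calls = planted_calls(noise_sd=0.05, seed=6)
    for c in calls:
        assert 0.0 < c.cluster_p <= 1.0
        assert 0.0 < c.q_value <= 1.0
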