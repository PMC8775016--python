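"""Per-cluster condition-pattern comparison and DEP/ODEP/SEP calling.

Each cluster's replicate-averaged profiles are split by condition, the time
course of every gene is rank-discretized into a small number of
equal-frequency levels per condition, and every pair of conditions is tested
for pattern similarity.  The comparison pools the paired level sequences
``{(level[g, a, t], level[g, b, t])}`` over all genes g and time points t of
the cluster.

Two pairwise statistics are computed:

* ``nmi`` — plug-in mutual information between the paired level sequences,
  normalized by the mean marginal entropy.  It is reported descriptively and
  can drive the permutation test; being invariant to any relabelling of
  levels, it scores *dependence*, not agreement (a perfectly inverted pattern
  has NMI 1).
* ``agreement`` — the fraction of positions where the two level sequences
  coincide.  This is the default test statistic for the similar/different
  verdict: two conditions are called *similar* when their aligned agreement
  is significantly higher than under the null that one condition's time
  labels are randomly permuted within each gene.

Verdicts at level alpha are combined into a cluster label: SEP when all
condition pairs are similar, DEP when all pairs differ, ODEP when exactly one
condition differs from every other while the rest are mutually similar, and
``mixed`` otherwise.  A conservative composite cluster p-value (the worst
per-pair evidence for the assigned label) is corrected across clusters with
Benjamini-Hochberg, and only sufficiently large, significant, non-mixed
clusters are reported as final calls.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterResult
from .preprocess import TimeCourseTensor

__all__ = [
    "PairwiseSimilarity",
    "PatternCall",
    "discretize_cluster",
    "pairwise_nmi",
    "agreement_score",
    "permutation_p",
    "classify_cluster",
    "call_patterns",
]

DEFAULT_BINS = 3
DEFAULT_N_PERM = 1000
# Effect-size floor for a "similar" verdict: at least half of all pooled
# (gene, timepoint) positions must share a level.  Statistical significance
# alone is not enough, because partially related patterns (e.g. two peaks at
# different times sharing a common baseline) agree slightly but reliably
# above the permutation null once many genes are pooled.
DEFAULT_MIN_AGREEMENT = 0.5


@dataclass
class PairwiseSimilarity:
    """Similarity evidence for one pair of conditions within a cluster."""

    condition_a: str
    condition_b: str
    nmi: float
    agreement: float
    p_value: float
    verdict: str  # "similar" | "different"


@dataclass
class PatternCall:
    """Final pattern label for one cluster."""

    cluster_id: int
    label: str                      # "DEP" | "ODEP" | "SEP" | "mixed"
    odep_condition: str | None
    size: int
    pairwise: list[PairwiseSimilarity] = field(default_factory=list)
    cluster_p: float = 1.0
    q_value: float = 1.0
    significant: bool = False


def discretize_cluster(t: TimeCourseTensor, gene_subset, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Rank-discretize each gene's per-condition time course into equal-frequency levels.

    For every gene and condition the T values are ranked (ties get the lowest
    shared rank) and mapped to ``bins`` levels; the result is an integer array
    of shape (len(gene_subset), C, T) with values in [0, bins).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    n_t = len(t.timepoints)
    if n_t < bins:
        raise ValueError(
            f"{n_t} time points cannot support {bins} levels; use fewer bins"
        )
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise ValueError("gene_subset is empty")
    index = {g: i for i, g in enumerate(t.gene_ids)}
    rows = [index[g] for g in gene_subset]
    sub = t.values[rows]  # (G, C, T)
    ranks = rankdata(sub, method="min", axis=2)  # ties share the lower rank/level
    levels = ((ranks - 1) * bins) // n_t
    return levels.astype(int)


def _paired_levels(levels: np.ndarray, cond_a: int, cond_b: int) -> tuple[np.ndarray, np.ndarray]:
    return levels[:, cond_a, :], levels[:, cond_b, :]


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / (pa @ pb)[mask])).sum())


def pairwise_nmi(levels: np.ndarray, cond_a: int, cond_b: int, bins: int | None = None) -> float:
    """Plug-in NMI between two conditions' pooled level sequences.

    Normalization is by the mean of the two marginal entropies.  If both
    marginals are degenerate (constant sequences) the NMI is 1 when the
    sequences are equal and 0 otherwise; if exactly one marginal is
    degenerate the NMI is 0.
    """
    a, b = _paired_levels(levels, cond_a, cond_b)
    a = a.ravel()
    b = b.ravel()
    if bins is None:
        bins = int(max(a.max(initial=0), b.max(initial=0))) + 1
    joint = np.zeros((bins, bins))
    np.add.at(joint, (a, b), 1.0)
    h_a = _entropy(joint.sum(axis=1))
    h_b = _entropy(joint.sum(axis=0))
    if h_a == 0.0 and h_b == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    return _mutual_information(joint) / ((h_a + h_b) / 2.0)


def agreement_score(levels: np.ndarray, cond_a: int, cond_b: int) -> float:
    """Fraction of (gene, timepoint) positions where the two level sequences agree."""
    a, b = _paired_levels(levels, cond_a, cond_b)
    return float(np.mean(a == b))


def _gene_rng(rng_seed: int, gene_key: str, cond_a_key: str, cond_b_key: str) -> np.random.Generator:
    # Seeding by content (gene id and condition names) makes p-values invariant
    # to gene order and to condition reordering, while staying deterministic.
    entropy = [
        int(rng_seed) % (2**31),
        zlib.crc32(gene_key.encode()),
        zlib.crc32(cond_a_key.encode()),
        zlib.crc32(cond_b_key.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _null_b_levels(
    b: np.ndarray,
    n_perm: int,
    rng_seed: int,
    gene_keys: list[str],
    pair_keys: tuple[str, str],
) -> np.ndarray:
    """Null level sequences: cond_b's time labels permuted independently per gene.

    Returns an array of shape (G, n_perm, T).
    """
    n_genes, n_t = b.shape
    out = np.empty((n_genes, n_perm, n_t), dtype=b.dtype)
    base = np.tile(np.arange(n_t), (n_perm, 1))
    for g in range(n_genes):
        rng = _gene_rng(rng_seed, gene_keys[g], pair_keys[0], pair_keys[1])
        perms = rng.permuted(base, axis=1)
        out[g] = b[g][perms]
    return out


def _null_nmi(a: np.ndarray, b_null: np.ndarray, bins: int) -> np.ndarray:
    n_genes, n_perm, n_t = b_null.shape
    codes = (a[:, None, :] * bins + b_null).transpose(1, 0, 2).reshape(n_perm, -1)
    offsets = np.arange(n_perm)[:, None] * (bins * bins)
    counts = np.bincount((codes + offsets).ravel(), minlength=n_perm * bins * bins)
    joint = counts.reshape(n_perm, bins, bins).astype(float)
    n = n_genes * n_t
    p = joint / n
    pa = p.sum(axis=2, keepdims=True)
    pb = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (pa * pb)), 0.0)
    mi = terms.sum(axis=(1, 2))
    h_a = np.array([_entropy(row) for row in pa[:, :, 0]])
    h_b = np.array([_entropy(row) for row in pb[:, 0, :]])
    denom = (h_a + h_b) / 2.0
    out = np.zeros(n_perm)
    ok = denom > 0
    out[ok] = mi[ok] / denom[ok]
    # degenerate permutations (both marginals constant): NMI 1 iff sequences equal
    both_const = (h_a == 0) & (h_b == 0)
    if both_const.any():
        equal = (b_null.transpose(1, 0, 2)[both_const] == a[None, :, :]).all(axis=(1, 2))
        out[both_const] = equal.astype(float)
    return out


def permutation_p(
    levels: np.ndarray,
    cond_a: int,
    cond_b: int,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    statistic: str = "agreement",
    bins: int | None = None,
    gene_keys: list[str] | None = None,
    condition_keys: list[str] | None = None,
) -> float:
    """One-sided permutation p-value for pairwise pattern similarity.

    The null distribution permutes cond_b's T time labels independently within
    each gene; ``p = (1 + #{null >= observed}) / (n_perm + 1)``.  The test
    statistic is aligned level agreement by default, or plug-in NMI with
    ``statistic="nmi"``.  Deterministic given ``rng_seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if statistic not in ("agreement", "nmi"):
        raise ValueError(f"unknown statistic {statistic!r}")
    a, b = _paired_levels(levels, cond_a, cond_b)
    n_genes = a.shape[0]
    if gene_keys is None:
        gene_keys = [f"gene{i}" for i in range(n_genes)]
    if condition_keys is None:
        condition_keys = [f"cond{i}" for i in range(levels.shape[1])]
    pair_keys = (condition_keys[cond_a], condition_keys[cond_b])
    if bins is None:
        bins = int(max(a.max(initial=0), b.max(initial=0))) + 1

    b_null = _null_b_levels(b, n_perm, rng_seed, gene_keys, pair_keys)
    if statistic == "agreement":
        observed = float(np.mean(a == b))
        null = np.mean(a[:, None, :] == b_null, axis=(0, 2))
    else:
        observed = pairwise_nmi(levels, cond_a, cond_b, bins=bins)
        null = _null_nmi(a, b_null, bins)
    exceed = int(np.sum(null >= observed - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def classify_cluster(
    pairwise: list[PairwiseSimilarity], conditions: list[str]
) -> tuple[str, str | None]:
    """Combine pairwise verdicts into a cluster label.

    SEP when every pair is similar; DEP when every pair differs; ODEP when
    exactly one condition differs from all others while the remaining pairs
    are mutually similar; ``mixed`` otherwise.
    """
    expected = len(conditions) * (len(conditions) - 1) // 2
    if len(pairwise) != expected:
        raise ValueError(f"expected {expected} condition pairs, got {len(pairwise)}")
    different = {
        frozenset((p.condition_a, p.condition_b)) for p in pairwise if p.verdict == "different"
    }
    if not different:
        return "SEP", None
    if len(different) == expected:
        return "DEP", None
    candidates = []
    for x in conditions:
        pairs_with_x = {frozenset((x, c)) for c in conditions if c != x}
        if pairs_with_x == different:
            candidates.append(x)
    if len(candidates) == 1:
        return "ODEP", candidates[0]
    return "mixed", None


def call_patterns(
    t: TimeCourseTensor,
    clusters: ClusterResult,
    alpha: float = 0.05,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    min_cluster_size: int = 5,
    bins: int = DEFAULT_BINS,
    statistic: str = "agreement",
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
    profile_gene_ids: list[str] | None = None,
) -> list[PatternCall]:
    """Label every cluster DEP/ODEP/SEP/mixed with multiplicity-corrected significance.

    ``profile_gene_ids`` maps cluster assignments to gene IDs when the
    clustered profiles exclude genes of the tensor (zero-norm drops); by
    default the tensor's own gene order is used.

    The composite cluster p is the worst per-pair evidence for the assigned
    label: the largest p among pairs required similar, and the largest (1 - p)
    among pairs required different.  Benjamini-Hochberg adjusts these across
    clusters; ``significant`` requires a non-mixed label, q <= alpha and at
    least ``min_cluster_size`` genes.  Undersized clusters are labelled mixed
    and excluded from testing.
    """
    gene_ids = profile_gene_ids if profile_gene_ids is not None else t.gene_ids
    if len(gene_ids) != len(clusters.assignments):
        raise ValueError("gene id list does not match cluster assignments")
    conditions = t.conditions
    n_cond = len(conditions)
    p_floor = 1.0 / (n_perm + 1)

    calls: list[PatternCall] = []
    tested: list[PatternCall] = []
    for cid in range(clusters.n_clusters):
        members = [g for g, a in zip(gene_ids, clusters.assignments) if a == cid]
        if len(members) < min_cluster_size:
            calls.append(PatternCall(cid, "mixed", None, len(members)))
            continue
        levels = discretize_cluster(t, members, bins=bins)
        pairwise: list[PairwiseSimilarity] = []
        for i in range(n_cond):
            for j in range(i + 1, n_cond):
                a, b = _paired_levels(levels, i, j)
                if np.all(a == a.flat[0]) and np.array_equal(a, b):
                    # Both conditions are flat in every gene: the permutation
                    # null is a point mass and the test has no power.  Equal
                    # constant sequences are similar by convention.
                    pairwise.append(PairwiseSimilarity(
                        conditions[i], conditions[j], 1.0, 1.0, p_floor, "similar"
                    ))
                    continue
                p = permutation_p(
                    levels, i, j, n_perm=n_perm, rng_seed=rng_seed,
                    statistic=statistic, bins=bins,
                    gene_keys=members, condition_keys=conditions,
                )
                nmi = pairwise_nmi(levels, i, j, bins=bins)
                agree = agreement_score(levels, i, j)
                verdict = "similar" if (p <= alpha and agree >= min_agreement) else "different"
                pairwise.append(
                    PairwiseSimilarity(conditions[i], conditions[j], nmi, agree, p, verdict)
                )
        label, odep_condition = classify_cluster(pairwise, conditions)
        # Composite evidence for the assigned label: the worst similar pair
        # (its p) combined with the best different pair (its 1 - p).  A label
        # with different pairs only needs one of them to be convincingly
        # non-similar, whereas every similar pair must hold up.
        similar_p = [p.p_value for p in pairwise if p.verdict == "similar"]
        different_p = [1.0 - p.p_value for p in pairwise if p.verdict == "different"]
        components = []
        if similar_p:
            components.append(max(similar_p))
        if different_p:
            components.append(min(different_p))
        cluster_p = min(1.0, max(max(components), p_floor))
        call = PatternCall(cid, label, odep_condition, len(members), pairwise, cluster_p)
        calls.append(call)
        tested.append(call)

    if tested:
        _, q_values, _, _ = multipletests([c.cluster_p for c in tested], method="fdr_bh")
        for call, q in zip(tested, q_values):
            call.q_value = float(min(1.0, q))
            call.significant = (
                call.label != "mixed" and call.q_value <= alpha and call.size >= min_cluster_size
            )
    return calls
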