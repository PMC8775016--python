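"""End-to-end orchestration: read -> preprocess -> cluster -> classify -> annotate.

``run_pipeline`` executes the whole analysis from a :class:`RunConfig` and
writes a result bundle to the output directory:

* ``summary.json`` — detected (conditions, timepoints, replicates), gene
  counts before/after each filter, the K used, per-type cluster and gene
  counts, and every parameter in effect;
* ``clusters.tsv`` — gene-to-cluster assignments;
* ``patterns.tsv`` — per-cluster DEP/ODEP/SEP calls with p- and q-values;
* ``pairwise.tsv`` — per condition pair NMI, agreement and permutation p;
* ``centroids.tsv`` — cluster centroids over condition:timepoint columns;
* ``ktest.tsv`` — K grid and mean WCSS (when the K test runs);
* ``enrichment.tsv`` / ``tf.tsv`` / ``mirna.tsv`` — when annotation tables
  are supplied;
* ``plots/cluster_*.png`` — per-cluster mean patterns (unless disabled).

Every stochastic step is seeded from ``rng_seed``, and all text outputs are
written deterministically, so identical configurations produce byte-identical
bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, enrichment, ktest, patterns, preprocess
from .io import ExpressionMatrix, ValidationError, merge_condition_files, read_expression_file

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("timepatterns")


@dataclass
class RunConfig:
    """All parameters of one analysis run.

    Exactly one of ``k`` (fixed cluster count) or ``ktest_kmax`` (elbow-based
    recommendation) must be set.
    """

    inputs: list[str]
    output_dir: str
    data_type: str = "rnaseq"
    normalize: bool = True
    protein_coding_only: bool = False
    biotype_table: str | None = None
    k: int | None = None
    ktest_kmax: int | None = None
    alpha: float = 0.05
    n_perm: int = 1000
    repeats: int = 5
    n_restarts: int = 5
    min_cluster_size: int = 5
    bins: int = 3
    subsample_fraction: float = 0.1
    rng_seed: int = 0
    tf_list: str | None = None
    mirna_targets: str | None = None
    gene_sets: str | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValidationError("at least one input file is required")
        if (self.k is None) == (self.ktest_kmax is None):
            raise ValidationError(
                "exactly one of a fixed K or the K test (kmax) must be chosen; "
                "if unsure, run the K test or start with a large K (e.g. 100)"
            )
        if self.protein_coding_only and not self.biotype_table:
            raise ValidationError("protein-coding filtering requires a biotype table")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML/JSON config file; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the result bundle; returns the summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # output_dir is where the bundle lands, not an analysis parameter; leaving
    # it out keeps summary.json identical across runs into different directories
    parameters = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    summary: dict = {"parameters": parameters}

    logger.info("reading %d input file(s)", len(config.inputs))
    matrices = [read_expression_file(p, config.data_type) for p in config.inputs]
    merged = merge_condition_files(matrices)
    n_cond, n_tp, n_rep = merged.detected_counts()
    summary["detected"] = {"conditions": n_cond, "timepoints": n_tp, "replicates": n_rep}
    summary["genes_input"] = len(merged.gene_ids)
    logger.info("detected %d conditions x %d timepoints x %d replicates, %d genes",
                n_cond, n_tp, n_rep, len(merged.gene_ids))

    averaged = preprocess.average_replicates(merged)
    normalized = preprocess.normalize(averaged, enabled=config.normalize)
    annotation = (
        preprocess.read_annotation_table(config.biotype_table)
        if config.biotype_table else None
    )
    filtered, filter_report = preprocess.filter_protein_coding(
        normalized, annotation, enabled=config.protein_coding_only
    )
    summary["protein_coding_filter"] = filter_report
    summary["genes_after_filter"] = len(filtered.gene_ids)

    tensor = preprocess.to_tensor(filtered)
    profiles, dropped_zero = preprocess.flatten_to_unit_profiles(tensor)
    summary["genes_dropped_zero_norm"] = len(dropped_zero)
    summary["genes_clustered"] = profiles.n_genes
    if profiles.n_genes == 0:
        raise ValidationError("no genes left to cluster after preprocessing")

    if config.ktest_kmax is not None:
        logger.info("running K test up to kmax=%d", config.ktest_kmax)
        kt = ktest.run_k_test(
            profiles, config.ktest_kmax, repeats=config.repeats,
            rng_seed=config.rng_seed, subsample_fraction=config.subsample_fraction,
        )
        _write_tsv(pd.DataFrame({"K": kt.k_grid, "mean_wcss": kt.mean_wcss}),
                   outdir / "ktest.tsv")
        summary["ktest"] = {
            "recommended_k": kt.recommended_k,
            "elbow_strength": kt.elbow_strength,
            "no_clear_elbow": kt.no_clear_elbow,
        }
        k_used = kt.recommended_k
    else:
        k_used = config.k
    summary["k_used"] = k_used

    logger.info("clustering %d genes with K=%d", profiles.n_genes, k_used)
    result = clustering.spherical_kmeans(
        profiles, k_used, rng_seed=config.rng_seed,
        n_restarts=config.n_restarts, subsample_fraction=config.subsample_fraction,
    )
    summary["clusters_nonempty"] = result.n_clusters
    summary["objective"] = result.objective
    summary["wcss"] = result.inertia

    calls = patterns.call_patterns(
        tensor, result, alpha=config.alpha, n_perm=config.n_perm,
        rng_seed=config.rng_seed, min_cluster_size=config.min_cluster_size,
        bins=config.bins, profile_gene_ids=profiles.gene_ids,
    )

    assignments = pd.DataFrame({
        "gene_id": profiles.gene_ids,
        "cluster": result.assignments,
    })
    _write_tsv(assignments, outdir / "clusters.tsv")

    centroid_df = pd.DataFrame(result.centroids, columns=profiles.column_labels())
    centroid_df.insert(0, "cluster", np.arange(result.n_clusters))
    _write_tsv(centroid_df, outdir / "centroids.tsv")

    _write_tsv(pd.DataFrame([
        {
            "cluster_id": c.cluster_id, "label": c.label,
            "odep_condition": c.odep_condition or "", "size": c.size,
            "cluster_p": c.cluster_p, "q_value": c.q_value, "significant": c.significant,
        }
        for c in calls
    ]), outdir / "patterns.tsv")

    _write_tsv(pd.DataFrame([
        {
            "cluster_id": c.cluster_id, "cond_a": p.condition_a, "cond_b": p.condition_b,
            "nmi": p.nmi, "agreement": p.agreement, "p": p.p_value, "verdict": p.verdict,
        }
        for c in calls for p in c.pairwise
    ]), outdir / "pairwise.tsv")

    significant = [c for c in calls if c.significant]
    genes_by_type: dict[str, list[str]] = {t: [] for t in ("DEP", "ODEP", "SEP")}
    cluster_genes = {
        cid: [g for g, a in zip(profiles.gene_ids, result.assignments) if a == cid]
        for cid in range(result.n_clusters)
    }
    for c in significant:
        genes_by_type[c.label].extend(cluster_genes[c.cluster_id])
    summary["pattern_counts"] = {
        t: {
            "clusters": sum(1 for c in significant if c.label == t),
            "genes": len(genes_by_type[t]),
        }
        for t in ("DEP", "ODEP", "SEP")
    }
    summary["significant_clusters"] = len(significant)

    if config.tf_list or config.mirna_targets:
        tables = enrichment.RegulatorTables(
            tf_genes=enrichment.read_tf_list(config.tf_list) if config.tf_list else set(),
            mirna_targets=(
                enrichment.read_mirna_targets(config.mirna_targets)
                if config.mirna_targets else []
            ),
        )
        if config.tf_list:
            _write_tsv(pd.DataFrame([
                {"cluster_id": cid, "gene_id": g}
                for cid, genes in sorted(cluster_genes.items())
                for g in enrichment.annotate_tfs(genes, tables)
            ], columns=["cluster_id", "gene_id"]), outdir / "tf.tsv")
        if config.mirna_targets:
            rows, counts = [], {}
            for cid, genes in sorted(cluster_genes.items()):
                hits, n_mirnas = enrichment.annotate_mirna_targets(genes, tables)
                counts[cid] = n_mirnas
                rows.extend(
                    {"cluster_id": cid, "gene_id": g, "mirnas": ",".join(ms)}
                    for g, ms in hits
                )
            _write_tsv(pd.DataFrame(rows, columns=["cluster_id", "gene_id", "mirnas"]),
                       outdir / "mirna.tsv")
            summary["mirna_counts_per_cluster"] = counts

    if config.gene_sets:
        collection = enrichment.read_gmt(config.gene_sets, universe=profiles.gene_ids)
        enriched = enrichment.enrich_cluster_type(
            {t: genes for t, genes in genes_by_type.items() if genes},
            collection, alpha=config.alpha,
        )
        _write_tsv(enriched, outdir / "enrichment.tsv")

    if config.make_plots:
        from .plotting import plot_cluster_patterns

        plot_cluster_patterns(
            tensor, result, outdir / "plots",
            profile_gene_ids=profiles.gene_ids,
            labels={c.cluster_id: c.label for c in calls},
        )

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
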