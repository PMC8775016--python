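"""Offline biological annotation: TF membership, miRNA targets, gene-set enrichment.

Regulator and gene-set information comes from user-supplied tables (a TF gene
list, a miRNA-target pair table, and gene sets in GMT format) rather than
live database queries, so results are reproducible against a pinned database
version.  Enrichment is a one-sided hypergeometric tail test on the overlap
between each aggregated cluster-type gene list (all DEP genes, all ODEP
genes, all SEP genes) and each gene set, Benjamini-Hochberg corrected within
each cluster type.  Aggregating by cluster type rather than per cluster keeps
the query lists large enough for enrichment to have power, since single
clusters are often small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegulatorTables",
    "GeneSetCollection",
    "read_tf_list",
    "read_mirna_targets",
    "read_gmt",
    "annotate_tfs",
    "annotate_mirna_targets",
    "hypergeometric_p",
    "enrich_cluster_type",
]


@dataclass
class RegulatorTables:
    """Offline regulator knowledge: TF genes and miRNA-target pairs."""

    tf_genes: set[str] = field(default_factory=set)
    mirna_targets: list[tuple[str, str, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for rec in self.mirna_targets:
            mirna, target = rec[0], rec[1]
            if not mirna or not target:
                raise ValueError("miRNA-target records must have non-empty identifiers")
            if (mirna, target) in seen:
                continue
            seen.add((mirna, target))
            deduped.append(rec)
        self.mirna_targets = deduped

    def targets_by_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for mirna, target, *_ in self.mirna_targets:
            out.setdefault(target, []).append(mirna)
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, plus the background universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: set[str]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")


def read_tf_list(path: str | Path) -> set[str]:
    """Read a TF gene list: one identifier per line (blank lines ignored)."""
    genes = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.add(g)
    return genes


def read_mirna_targets(path: str | Path) -> list[tuple[str, str, float | None]]:
    """Read a 2-3 column TSV of (mirna, target_gene[, score]) pairs."""
    records: list[tuple[str, str, float | None]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno} needs at least 2 tab-separated columns")
            score = float(parts[2]) if len(parts) > 2 and parts[2] != "" else None
            records.append((parts[0], parts[1], score))
    return records


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read gene sets in GMT format: set_id <tab> description <tab> member genes...

    The universe defaults to the union of all set members; pass the analysed
    gene list instead to test enrichment against the experiment background.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need id, description, >=1 gene")
            set_id, description = parts[0], parts[1]
            members = frozenset(g for g in parts[2:] if g)
            if set_id in sets:
                raise ValueError(f"{path}: duplicate set id {set_id!r} at line {lineno}")
            sets[set_id] = (description, members)
    if universe is None:
        uni: set[str] = set()
        for _, members in sets.values():
            uni |= members
    else:
        uni = set(universe)
    return GeneSetCollection(sets, uni)


def annotate_tfs(cluster_genes: Sequence[str], tables: RegulatorTables) -> list[str]:
    """TF genes present in the cluster, in input order, deduplicated."""
    seen: set[str] = set()
    out = []
    for g in cluster_genes:
        if g in tables.tf_genes and g not in seen:
            out.append(g)
        seen.add(g)
    return out


def annotate_mirna_targets(
    cluster_genes: Sequence[str], tables: RegulatorTables
) -> tuple[list[tuple[str, list[str]]], int]:
    """Cluster genes with at least one known targeting miRNA, plus a distinct-miRNA count."""
    by_gene = tables.targets_by_gene()
    seen: set[str] = set()
    out: list[tuple[str, list[str]]] = []
    for g in cluster_genes:
        if g in seen:
            continue
        seen.add(g)
        if g in by_gene:
            out.append((g, sorted(by_gene[g])))
    distinct = len({m for _, mirnas in out for m in mirnas})
    return out, distinct


def hypergeometric_p(universe_size: int, set_size: int, query_size: int, overlap: int) -> float:
    """One-sided tail P[X >= overlap] with X ~ Hypergeom(N, K, n)."""
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def enrich_cluster_type(
    genes_by_type: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each gene set against each cluster-type gene list.

    Query genes outside the universe are dropped (counted in the
    ``dropped_from_universe`` column).  p-values are BH-adjusted within each
    cluster type; rows with adjusted p <= alpha carry ``significant=True``.
    """
    universe = collection.universe
    n_universe = len(universe)
    rows = []
    for ctype in genes_by_type:
        query_all = set(genes_by_type[ctype])
        query = query_all & universe
        dropped = len(query_all) - len(query)
        if len(query) > n_universe:
            raise ValueError("query set larger than universe")
        for set_id, (description, members) in collection.sets.items():
            members_in_universe = members & universe
            overlap = len(query & members_in_universe)
            p = hypergeometric_p(n_universe, len(members_in_universe), len(query), overlap)
            rows.append({
                "type": ctype,
                "set_id": set_id,
                "description": description,
                "overlap": overlap,
                "set_size": len(members_in_universe),
                "query_size": len(query),
                "universe_size": n_universe,
                "dropped_from_universe": dropped,
                "p": p,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(p_adj=[], neg_log10_p_adj=[], significant=[])
    df["p_adj"] = 1.0
    for ctype, group in df.groupby("type"):
        _, q, _, _ = multipletests(group["p"], method="fdr_bh")
        df.loc[group.index, "p_adj"] = np.minimum(q, 1.0)
    df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
    df["significant"] = df["p_adj"] <= alpha
    return df.reset_index(drop=True)
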