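"""Replicate averaging, normalization, gene filtering and unit-vector projection.

The preprocessing pipeline runs, in order: replicate averaging, optional
normalization, optional protein-coding filtering, rearrangement into a
(gene, condition, timepoint) tensor, and finally condition-major flattening
with projection onto the unit sphere — the geometry spherical K-means
clusters in.  Averaging precedes normalization so that normalization acts on
the condition/time-point columns actually analysed downstream.

Normalization for RNA-seq data is ``log2(x + 1)``, followed by scaling every
sample's column sum to the median column sum ("sample normalization"), then
quantile normalization across samples.  Microarray data gets quantile
normalization only; upstream platform normalization is assumed.  Both steps
can be disabled when the user has already normalized the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .io import ExpressionMatrix, SampleKey, ValidationError

__all__ = [
    "TimeCourseTensor",
    "UnitProfileMatrix",
    "GeneAnnotationTable",
    "read_annotation_table",
    "average_replicates",
    "quantile_normalize",
    "normalize",
    "filter_protein_coding",
    "to_tensor",
    "flatten_to_unit_profiles",
]

ZERO_NORM_TOL = 1e-12


@dataclass
class TimeCourseTensor:
    """Replicate-averaged expression as a (genes x conditions x timepoints) array."""

    gene_ids: list[str]
    conditions: list[str]
    timepoints: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.gene_ids), len(self.conditions), len(self.timepoints))
        if self.values.shape != expected:
            raise ValidationError(f"tensor shape {self.values.shape} != {expected}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("duplicate condition labels")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValidationError("duplicate timepoint labels")
        if len(self.conditions) < 2:
            raise ValidationError("multi-condition analysis requires at least 2 conditions")
        if len(self.timepoints) < 2:
            raise ValidationError("time-course analysis requires at least 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("tensor contains non-finite values")

    def condition_index(self, name: str) -> int:
        try:
            return self.conditions.index(name)
        except ValueError:
            raise KeyError(f"unknown condition {name!r}") from None


@dataclass
class UnitProfileMatrix:
    """Per-gene condition-major concatenated profiles, each row unit Euclidean norm.

    Row layout: all T time points of condition 1, then condition 2, and so on.
    """

    gene_ids: list[str]
    vectors: np.ndarray
    conditions: list[str]
    timepoints: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        ct = len(self.conditions) * len(self.timepoints)
        if self.vectors.shape != (len(self.gene_ids), ct):
            raise ValidationError(
                f"profile shape {self.vectors.shape} != ({len(self.gene_ids)}, {ct})"
            )
        if self.vectors.size:
            norms = np.linalg.norm(self.vectors, axis=1)
            if np.max(np.abs(norms - 1.0)) > 1e-9:
                raise ValidationError("profile rows are not unit-norm")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def column_labels(self) -> list[str]:
        return [f"{c}:{t}" for c in self.conditions for t in self.timepoints]


@dataclass
class GeneAnnotationTable:
    """Mapping from input gene IDs to canonical IDs, symbols and biotypes."""

    rows: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def biotype(self, gene_id: str) -> str | None:
        entry = self.rows.get(gene_id)
        return entry[2] if entry else None

    def __len__(self) -> int:
        return len(self.rows)


def read_annotation_table(path: str | Path) -> GeneAnnotationTable:
    """Read a 4-column TSV: gene_id, canonical_id, symbol, biotype (with header)."""
    rows: dict[str, tuple[str, str, str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:4]] != ["gene_id", "canonical_id", "symbol", "biotype"]:
            raise ValidationError(
                f"{path}: expected header 'gene_id canonical_id symbol biotype', got {header[:4]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}: line {lineno} has fewer than 4 columns")
            gid = parts[0]
            if gid in rows:
                raise ValidationError(f"{path}: duplicate gene_id {gid!r} at line {lineno}")
            rows[gid] = (parts[1], parts[2], parts[3])
    return GeneAnnotationTable(rows)


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate columns to their arithmetic mean per (condition, timepoint)."""
    groups: dict[tuple[str, str], list[int]] = {}
    order: list[tuple[str, str]] = []
    for j, k in enumerate(m.sample_keys):
        key = (k.condition, k.timepoint)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(j)
    keys = [SampleKey(c, t, None) for c, t in order]
    values = np.column_stack([m.values[:, groups[k]].mean(axis=1) for k in order]) \
        if order else np.empty((len(m.gene_ids), 0))
    return ExpressionMatrix(list(m.gene_ids), keys, values, m.data_type)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force all sample columns to share a common distribution by rank averaging.

    Each rank's reference value is the mean across samples of the sorted
    columns; tied values receive the mean of the reference values their tied
    ranks span (the usual microarray convention).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return out


def normalize(m: ExpressionMatrix, enabled: bool = True) -> ExpressionMatrix:
    """Normalize a (replicate-averaged) matrix; identity when disabled."""
    if not enabled:
        return m
    values = m.values
    if m.data_type == "rnaseq":
        if values.size and values.min() < 0:
            raise ValidationError("negative values are not allowed for rnaseq data")
        values = np.log2(values + 1.0)
        totals = values.sum(axis=0)
        target = np.median(totals)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(totals > 0, target / totals, 1.0)
        values = values * scale
    values = quantile_normalize(values)
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_keys), values, m.data_type)


def filter_protein_coding(
    m: ExpressionMatrix,
    annotation: GeneAnnotationTable | None = None,
    enabled: bool = True,
) -> tuple[ExpressionMatrix, dict]:
    """Keep genes annotated as protein_coding; genes absent from the table are dropped.

    Returns the filtered matrix and a report of dropped counts.
    """
    if not enabled:
        return m, {"enabled": False, "kept": len(m.gene_ids),
                   "dropped_unannotated": 0, "dropped_noncoding": 0}
    if annotation is None:
        raise ValidationError("protein-coding filtering requires an annotation table")
    kept, unann, noncoding = [], 0, 0
    for g in m.gene_ids:
        bt = annotation.biotype(g)
        if bt is None:
            unann += 1
        elif bt == "protein_coding":
            kept.append(g)
        else:
            noncoding += 1
    report = {"enabled": True, "kept": len(kept),
              "dropped_unannotated": unann, "dropped_noncoding": noncoding}
    if not kept:
        raise ValidationError("protein-coding filter removed every gene (empty analysis set)")
    return m.subset_genes(kept), report


def to_tensor(m: ExpressionMatrix) -> TimeCourseTensor:
    """Rearrange a replicate-averaged matrix into a (gene, condition, timepoint) tensor."""
    if any(k.has_replicate for k in m.sample_keys):
        m = average_replicates(m)
    conditions = m.conditions
    timepoints = m.timepoints
    col = {(k.condition, k.timepoint): j for j, k in enumerate(m.sample_keys)}
    missing = [(c, t) for c in conditions for t in timepoints if (c, t) not in col]
    if missing:
        raise ValidationError(
            "missing condition/time-point combinations: "
            + ", ".join(f"{c}_{t}" for c, t in missing[:10])
        )
    values = np.empty((len(m.gene_ids), len(conditions), len(timepoints)))
    for ci, c in enumerate(conditions):
        for ti, t in enumerate(timepoints):
            values[:, ci, ti] = m.values[:, col[(c, t)]]
    return TimeCourseTensor(list(m.gene_ids), conditions, timepoints, values)


def flatten_to_unit_profiles(
    t: TimeCourseTensor, tol: float = ZERO_NORM_TOL
) -> tuple[UnitProfileMatrix, list[str]]:
    """Concatenate each gene condition-major and project onto the unit sphere.

    Genes whose concatenated vector has (near-)zero norm cannot be projected
    and are dropped; the second return value lists them.
    """
    flat = t.values.reshape(len(t.gene_ids), -1)
    norms = np.linalg.norm(flat, axis=1)
    keep = norms > tol
    dropped = [g for g, k in zip(t.gene_ids, keep) if not k]
    vectors = flat[keep] / norms[keep, None]
    gene_ids = [g for g, k in zip(t.gene_ids, keep) if k]
    return UnitProfileMatrix(gene_ids, vectors, list(t.conditions), list(t.timepoints)), dropped
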