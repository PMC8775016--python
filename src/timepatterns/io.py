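"""Reading, validating and merging time-course expression tables.

The expected file format is tab-delimited text whose first header field is
``GeneID`` and whose remaining header fields name each sample as
``<condition>_<timepoint>_<replicate>`` (for example ``DV10_Day2_rep1``), or
``<condition>_<timepoint>`` when the experiment has no replicates.  Underscores
are the only delimiter, so condition, time-point and replicate names must not
themselves contain underscores.  Condition and time-point order is the order of
first appearance in the header, never lexicographic (``day14`` would otherwise
sort before ``day3``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "SampleKey",
    "ExpressionMatrix",
    "parse_sample_header",
    "read_expression_file",
    "write_expression_file",
    "merge_condition_files",
]


class FormatError(ValueError):
    """Raised when an input file does not follow the expected syntax."""


class ValidationError(ValueError):
    """Raised when a syntactically valid input violates a semantic contract."""


@dataclass(frozen=True)
class SampleKey:
    """Identity of one sample column: condition, time point and (optionally) replicate."""

    condition: str
    timepoint: str
    replicate: str | None = None

    def __post_init__(self) -> None:
        for name, value in (("condition", self.condition), ("timepoint", self.timepoint)):
            if not value:
                raise FormatError(f"sample key has empty {name} field")
            if "\t" in value or "_" in value:
                raise FormatError(f"sample key {name} {value!r} contains a forbidden character")
        if self.replicate is not None and (not self.replicate or "_" in self.replicate):
            raise FormatError(f"sample key replicate {self.replicate!r} is malformed")

    @property
    def has_replicate(self) -> bool:
        return self.replicate is not None

    def label(self) -> str:
        if self.replicate is None:
            return f"{self.condition}_{self.timepoint}"
        return f"{self.condition}_{self.timepoint}_{self.replicate}"


def parse_sample_header(token: str) -> SampleKey:
    """Parse one header column into a :class:`SampleKey`.

    The token must split on underscores into exactly three fields
    (condition, timepoint, replicate) or exactly two (no replicates).
    """
    if not token:
        raise FormatError("empty sample header column")
    fields = token.split("_")
    if any(f == "" for f in fields):
        raise FormatError(f"sample header {token!r} contains an empty field")
    if len(fields) == 2:
        return SampleKey(fields[0], fields[1], None)
    if len(fields) == 3:
        return SampleKey(fields[0], fields[1], fields[2])
    raise FormatError(
        f"sample header {token!r} has {len(fields)} underscore-separated fields; expected 2 or 3"
    )


def _first_appearance(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for it in items:
        seen.setdefault(it, None)
    return list(seen)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with per-sample metadata.

    ``values`` holds expression on whatever scale the file provides (counts,
    RPKM/FPKM/TPM or microarray intensity); ``data_type`` records which of the
    two supported platforms produced it.
    """

    gene_ids: list[str]
    sample_keys: list[SampleKey]
    values: np.ndarray
    data_type: str = "rnaseq"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_keys)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_keys)} samples"
            )
        if self.data_type not in ("microarray", "rnaseq"):
            raise ValidationError(f"unknown data_type {self.data_type!r}")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene IDs: {', '.join(dup[:10])}")
        labels = [k.label() for k in self.sample_keys]
        dup = _duplicates(labels)
        if dup:
            raise ValidationError(f"duplicate sample columns: {', '.join(dup[:10])}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]}, "
                f"sample {labels[bad[1]]}"
            )
        if self.data_type == "rnaseq" and self.values.size and self.values.min() < 0:
            raise ValidationError("negative values are not allowed for rnaseq data")
        has_rep = {k.has_replicate for k in self.sample_keys}
        if len(has_rep) > 1:
            raise FormatError("file mixes sample headers with and without a replicate field")
        counts = self.replicate_structure()
        if len(set(counts.values())) > 1:
            raise ValidationError(
                "unequal replicate counts across condition/time-point pairs: "
                + ", ".join(f"{c}_{t}:{n}" for (c, t), n in sorted(counts.items()))
            )

    def replicate_structure(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for k in self.sample_keys:
            counts[(k.condition, k.timepoint)] = counts.get((k.condition, k.timepoint), 0) + 1
        return counts

    @property
    def conditions(self) -> list[str]:
        return _first_appearance(k.condition for k in self.sample_keys)

    @property
    def timepoints(self) -> list[str]:
        return _first_appearance(k.timepoint for k in self.sample_keys)

    @property
    def n_replicates(self) -> int:
        counts = self.replicate_structure()
        return next(iter(counts.values())) if counts else 0

    def detected_counts(self) -> tuple[int, int, int]:
        """(conditions, timepoints, replicates) as auto-detected from the header."""
        return len(self.conditions), len(self.timepoints), self.n_replicates

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_keys),
                                self.values[rows], self.data_type)


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for it in items:
        if it in seen and it not in dup:
            dup.append(it)
        seen.add(it)
    return dup


def read_expression_file(path: str | Path, data_type: str = "rnaseq") -> ExpressionMatrix:
    """Read and validate one tab-delimited expression file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
        if not header:
            raise FormatError(f"{path}: empty file")
        columns = header.split("\t")
        if columns[0] != "GeneID":
            raise FormatError(
                f"{path}: first header field must be 'GeneID', found {columns[0]!r}"
            )
        if len(columns) < 2:
            raise FormatError(f"{path}: header has no sample columns")
        keys = []
        for j, token in enumerate(columns[1:], start=2):
            try:
                keys.append(parse_sample_header(token))
            except FormatError as exc:
                raise FormatError(f"{path}: header column {j}: {exc}") from exc

        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {len(columns)}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError:
                for j, v in enumerate(parts[1:], start=2):
                    try:
                        float(v)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric value {v!r} at line {lineno}, column {j}"
                        ) from None
                raise
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(keys)))
    return ExpressionMatrix(gene_ids, keys, values, data_type)


def write_expression_file(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix back in the input format (full float precision, round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("GeneID\t" + "\t".join(k.label() for k in m.sample_keys) + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def merge_condition_files(files: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge per-condition matrices into one, aligning genes by ID.

    Requires identical gene sets, disjoint condition names, and equal
    time-point and replicate counts across files.  A single input is returned
    unchanged.
    """
    if not files:
        raise ValidationError("no input matrices to merge")
    if len(files) == 1:
        return files[0]
    first = files[0]
    ref_genes = set(first.gene_ids)
    seen_conditions: set[str] = set(first.conditions)
    for i, m in enumerate(files[1:], start=2):
        other = set(m.gene_ids)
        if other != ref_genes:
            diff = sorted(ref_genes.symmetric_difference(other))
            raise ValidationError(
                f"gene sets differ between file 1 and file {i}; "
                f"first mismatches: {', '.join(diff[:10])}"
            )
        overlap = seen_conditions.intersection(m.conditions)
        if overlap:
            raise ValidationError(f"condition names repeated across files: {sorted(overlap)}")
        seen_conditions.update(m.conditions)
        if len(m.timepoints) != len(first.timepoints):
            raise ValidationError(
                f"file {i} has {len(m.timepoints)} time points, "
                f"file 1 has {len(first.timepoints)}"
            )
        if m.n_replicates != first.n_replicates:
            raise ValidationError(
                f"file {i} has {m.n_replicates} replicates, file 1 has {first.n_replicates}"
            )
        if {k.has_replicate for k in m.sample_keys} != {k.has_replicate for k in first.sample_keys}:
            raise ValidationError("files mix replicate and no-replicate header dialects")

    gene_ids = list(first.gene_ids)
    blocks = [first.values]
    keys = list(first.sample_keys)
    for m in files[1:]:
        index = {g: i for i, g in enumerate(m.gene_ids)}
        order = [index[g] for g in gene_ids]
        blocks.append(m.values[order])
        keys.extend(m.sample_keys)
    data_types = {m.data_type for m in files}
    if len(data_types) > 1:
        raise ValidationError(f"files have mixed data types: {sorted(data_types)}")
    return ExpressionMatrix(gene_ids, keys, np.hstack(blocks), first.data_type)
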