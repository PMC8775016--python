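"""Synthetic multi-condition time-course datasets with planted pattern structure.

The generator plants gene clusters whose condition-level time templates
realise the three pattern classes: SEP clusters share one template across all
conditions, DEP clusters give every condition a distinct template (pairwise
template cosine <= 0.3, enforced), and ODEP clusters give one designated
condition a distinct template while the others share one.  Replicate values
are template plus Gaussian noise with standard deviation ``noise_sd *
amplitude``, shifted per gene to be non-negative, and written in the exact
tab-delimited input format (including the two-field no-replicate header
dialect when there is a single replicate), together with ground-truth
sidecar tables.

Template families are smooth shapes on [0, 1]-scaled time sampled at the T
time points: ``linear`` ramps, Gaussian ``peak`` bumps, ``sigmoid``
transitions and a flat ``constant``.  A ``phase`` parameter in [0, 1) selects
the variant (peak position, sigmoid midpoint/direction, ramp direction), and
DEP conditions are spread evenly in phase.  Not every family supports many
mutually distant variants — three or more conditions cannot get separated
linear or sigmoid templates, and constant templates cannot differ at all —
in which case generation fails with an explicit separation error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleKey, write_expression_file

__all__ = [
    "ClusterSpec",
    "FixtureSpec",
    "SyntheticDataset",
    "TemplateSeparationError",
    "generate",
    "canonical_fixture_spec",
]

PATTERN_TYPES = ("DEP", "ODEP", "SEP")
FAMILIES = ("linear", "peak", "sigmoid", "constant")
MAX_TEMPLATE_COSINE = 0.3
BASELINE_FACTOR = 1.2
GOLDEN = 0.6180339887498949


class TemplateSeparationError(ValueError):
    """Requested pattern cannot be realised with separated templates."""


@dataclass
class ClusterSpec:
    size: int
    pattern_type: str
    family: str
    amplitude: float = 1.0
    odep_condition: str | None = None
    phase: float | None = None  # default: golden-ratio sequence by cluster index

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if self.pattern_type not in PATTERN_TYPES:
            raise ValueError(f"pattern_type must be one of {PATTERN_TYPES}")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class FixtureSpec:
    n_conditions: int
    n_timepoints: int
    n_replicates: int
    clusters: list[ClusterSpec]
    n_background_genes: int = 0
    noise_sd: float = 0.05
    rng_seed: int = 0
    data_type: str = "rnaseq"
    mode: str = "continuous"  # or "counts" (Poisson draws around the template)

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in ("continuous", "counts"):
            raise ValueError("mode must be 'continuous' or 'counts'")

    @property
    def condition_names(self) -> list[str]:
        return [f"cond{i + 1}" for i in range(self.n_conditions)]

    @property
    def timepoint_names(self) -> list[str]:
        return [f"t{i + 1}" for i in range(self.n_timepoints)]

    @property
    def replicate_names(self) -> list[str] | None:
        if self.n_replicates == 1:
            return None  # single-replicate files use the two-field header dialect
        return [f"r{i + 1}" for i in range(self.n_replicates)]


def _template(family: str, phase: float, t: np.ndarray) -> np.ndarray:
    """Sample one centered, max-abs-normalized template at the T scaled time points."""
    u = phase % 1.0
    if family == "constant":
        return np.zeros_like(t)
    if family == "linear":
        s = (t - 0.5) if u < 0.5 else (0.5 - t)
    elif family == "peak":
        s = np.exp(-0.5 * ((t - u) / 0.1) ** 2)
    elif family == "sigmoid":
        direction = 1.0 if u < 0.5 else -1.0
        midpoint = 0.25 + (u % 0.5)
        s = direction * np.tanh((t - midpoint) / 0.2)
    else:  # pragma: no cover
        raise ValueError(family)
    s = s - s.mean()
    peak_abs = np.max(np.abs(s))
    if peak_abs == 0:
        raise TemplateSeparationError(
            f"{family} template with phase {phase} is flat at {len(t)} time points"
        )
    return s / peak_abs


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0  # flat templates are indistinguishable
    return float(a @ b / (na * nb))


def _condition_templates(
    cluster: ClusterSpec, spec: FixtureSpec, cluster_index: int
) -> np.ndarray:
    """(C, T) template array for one cluster, separation-checked for DEP/ODEP."""
    t = np.linspace(0.0, 1.0, spec.n_timepoints)
    c = spec.n_conditions
    phase = cluster.phase if cluster.phase is not None else (cluster_index * GOLDEN) % 1.0

    if cluster.pattern_type == "SEP":
        shared = _template(cluster.family, phase, t) if cluster.family != "constant" \
            else np.zeros_like(t)
        return np.tile(shared, (c, 1))

    if cluster.family == "constant":
        raise TemplateSeparationError(
            f"constant templates cannot differ between conditions ({cluster.pattern_type})"
        )

    if cluster.pattern_type == "DEP":
        templates = np.stack([_template(cluster.family, phase + i / c, t) for i in range(c)])
        check_pairs = [(i, j) for i in range(c) for j in range(i + 1, c)]
    else:  # ODEP
        if cluster.odep_condition is None:
            odep_idx = c - 1
        else:
            try:
                odep_idx = spec.condition_names.index(cluster.odep_condition)
            except ValueError:
                raise ValueError(
                    f"odep_condition {cluster.odep_condition!r} is not one of "
                    f"{spec.condition_names}"
                ) from None
        shared = _template(cluster.family, phase, t)
        different = _template(cluster.family, phase + 0.5, t)
        templates = np.tile(shared, (c, 1))
        templates[odep_idx] = different
        check_pairs = [(odep_idx, j) for j in range(c) if j != odep_idx]

    for i, j in check_pairs:
        cos = _cosine(templates[i], templates[j])
        if cos > MAX_TEMPLATE_COSINE:
            raise TemplateSeparationError(
                f"cluster {cluster_index} ({cluster.pattern_type}, {cluster.family}): "
                f"conditions {i + 1} and {j + 1} have template cosine {cos:.3f} "
                f"> {MAX_TEMPLATE_COSINE}; this family does not support "
                f"{spec.n_conditions} separated conditions"
            )
    return templates


@dataclass
class SyntheticDataset:
    """A generated dataset: expression matrix, ground truth, and the spec echo."""

    matrix: ExpressionMatrix
    truth: pd.DataFrame      # gene_id, cluster_id, pattern_type
    clusters: pd.DataFrame   # cluster_id, pattern_type, family, size, odep_condition, amplitude
    spec: FixtureSpec = field(repr=False, default=None)

    def write(self, outdir: str | Path, per_condition: bool = False) -> dict[str, Path]:
        """Write the expression file(s), ground-truth tables and spec echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if per_condition:
            for cond in self.matrix.conditions:
                cols = [j for j, k in enumerate(self.matrix.sample_keys) if k.condition == cond]
                sub = ExpressionMatrix(
                    list(self.matrix.gene_ids),
                    [self.matrix.sample_keys[j] for j in cols],
                    self.matrix.values[:, cols],
                    self.matrix.data_type,
                )
                p = outdir / f"expression_{cond}.tsv"
                write_expression_file(sub, p)
                paths[f"expression_{cond}"] = p
        else:
            p = outdir / "expression.tsv"
            write_expression_file(self.matrix, p)
            paths["expression"] = p
        tg = outdir / "ground_truth_genes.tsv"
        self.truth.to_csv(tg, sep="\t", index=False)
        paths["ground_truth_genes"] = tg
        tc = outdir / "ground_truth_clusters.tsv"
        self.clusters.to_csv(tc, sep="\t", index=False)
        paths["ground_truth_clusters"] = tc
        sp = outdir / "fixture_spec.json"
        echo = {
            "n_conditions": self.spec.n_conditions,
            "n_timepoints": self.spec.n_timepoints,
            "n_replicates": self.spec.n_replicates,
            "n_background_genes": self.spec.n_background_genes,
            "noise_sd": self.spec.noise_sd,
            "rng_seed": self.spec.rng_seed,
            "data_type": self.spec.data_type,
            "mode": self.spec.mode,
            "clusters": [
                {
                    "size": c.size, "pattern_type": c.pattern_type, "family": c.family,
                    "amplitude": c.amplitude, "odep_condition": c.odep_condition,
                    "phase": c.phase,
                }
                for c in self.spec.clusters
            ],
        }
        sp.write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        paths["fixture_spec"] = sp
        return paths


def generate(spec: FixtureSpec) -> SyntheticDataset:
    """Generate a planted dataset; deterministic (byte-identical files) given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
    c, n_t, r = spec.n_conditions, spec.n_timepoints, spec.n_replicates

    gene_ids: list[str] = []
    truth_rows = []
    cluster_rows = []
    blocks = []
    gene_counter = 0
    for ci, cluster in enumerate(spec.clusters):
        templates = _condition_templates(cluster, spec, ci)  # (C, T)
        a = cluster.amplitude
        mean = a * (BASELINE_FACTOR + templates)  # (C, T)
        noise = rng.normal(0.0, spec.noise_sd * a, size=(cluster.size, c, n_t, r))
        values = mean[None, :, :, None] + noise
        blocks.append(values)
        for _ in range(cluster.size):
            gid = f"TPG{gene_counter:05d}"
            gene_ids.append(gid)
            truth_rows.append({"gene_id": gid, "cluster_id": ci,
                               "pattern_type": cluster.pattern_type})
            gene_counter += 1
        cluster_rows.append({
            "cluster_id": ci, "pattern_type": cluster.pattern_type,
            "family": cluster.family, "size": cluster.size,
            "odep_condition": cluster.odep_condition or "", "amplitude": cluster.amplitude,
        })

    if spec.n_background_genes:
        amp = float(np.mean([cl.amplitude for cl in spec.clusters])) if spec.clusters else 1.0
        bg = rng.normal(BASELINE_FACTOR * amp, 0.4 * amp,
                        size=(spec.n_background_genes, c, n_t, r))
        blocks.append(bg)
        for _ in range(spec.n_background_genes):
            gid = f"TPB{gene_counter:05d}"
            gene_ids.append(gid)
            truth_rows.append({"gene_id": gid, "cluster_id": -1, "pattern_type": "background"})
            gene_counter += 1

    values = np.concatenate(blocks, axis=0) if blocks else np.empty((0, c, n_t, r))
    # shift each gene so its minimum is non-negative (rnaseq-valid)
    mins = values.reshape(len(gene_ids), -1).min(axis=1) if len(gene_ids) else np.array([])
    shift = np.where(mins < 0, -mins, 0.0)
    values = values + shift[:, None, None, None]
    if spec.mode == "counts":
        values = rng.poisson(values * 50.0).astype(float)

    rep_names = spec.replicate_names
    keys = []
    cols = []
    for cond_i, cond in enumerate(spec.condition_names):
        for tp_i, tp in enumerate(spec.timepoint_names):
            for rep_i in range(r):
                rep = rep_names[rep_i] if rep_names else None
                keys.append(SampleKey(cond, tp, rep))
                cols.append(values[:, cond_i, tp_i, rep_i])
    matrix = ExpressionMatrix(
        gene_ids, keys,
        np.column_stack(cols) if cols else np.empty((len(gene_ids), 0)),
        spec.data_type,
    )
    return SyntheticDataset(
        matrix=matrix,
        truth=pd.DataFrame(truth_rows, columns=["gene_id", "cluster_id", "pattern_type"]),
        clusters=pd.DataFrame(
            cluster_rows,
            columns=["cluster_id", "pattern_type", "family", "size",
                     "odep_condition", "amplitude"],
        ),
        spec=spec,
    )


def canonical_fixture_spec(
    noise_sd: float = 0.05,
    rng_seed: int = 0,
    cluster_size: int = 40,
    n_background_genes: int = 0,
) -> FixtureSpec:
    """The reference planted fixture: 3 conditions x 6 time points x 3 replicates,
    two clusters of each pattern type (DEP, ODEP, SEP)."""
    # Peak phases keep every peak center inside [0.1, 0.9]: at the time-axis
    # boundary a truncated peak degenerates into a monotone ramp whose rank
    # pattern collides with its neighbour condition's.
    clusters = [
        ClusterSpec(cluster_size, "DEP", "peak", phase=0.10),
        ClusterSpec(cluster_size, "DEP", "peak", phase=0.2333),
        ClusterSpec(cluster_size, "ODEP", "peak", odep_condition="cond3", phase=0.20),
        ClusterSpec(cluster_size, "ODEP", "peak", odep_condition="cond2", phase=0.45),
        ClusterSpec(cluster_size, "SEP", "linear", phase=0.0),
        ClusterSpec(cluster_size, "SEP", "sigmoid", phase=0.85),
    ]
    return FixtureSpec(
        n_conditions=3, n_timepoints=6, n_replicates=3, clusters=clusters,
        n_background_genes=n_background_genes, noise_sd=noise_sd, rng_seed=rng_seed,
    )
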