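"""Static per-cluster mean-pattern plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterResult
from .preprocess import TimeCourseTensor

__all__ = ["plot_cluster_patterns"]


def plot_cluster_patterns(
    t: TimeCourseTensor,
    clusters: ClusterResult,
    outdir: str | Path,
    profile_gene_ids: list[str] | None = None,
    labels: dict[int, str] | None = None,
) -> list[Path]:
    """Write one PNG per cluster showing each condition's mean time course."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_ids = profile_gene_ids if profile_gene_ids is not None else t.gene_ids
    index = {g: i for i, g in enumerate(t.gene_ids)}
    x = np.arange(len(t.timepoints))
    paths = []
    for cid in range(clusters.n_clusters):
        members = [index[g] for g, a in zip(gene_ids, clusters.assignments) if a == cid]
        if not members:
            continue
        mean = t.values[members].mean(axis=0)  # (C, T)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for ci, cond in enumerate(t.conditions):
            ax.plot(x, mean[ci], marker="o", label=cond)
        title = f"cluster {cid} (n={len(members)})"
        if labels and cid in labels:
            title += f" — {labels[cid]}"
        ax.set_title(title)
        ax.set_xticks(x)
        ax.set_xticklabels(t.timepoints, rotation=45, ha="right")
        ax.set_ylabel("mean expression")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"cluster_{cid:03d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
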