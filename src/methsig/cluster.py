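"""Hierarchical clustering of samples over a probe subset.

The default distance is 1 - Pearson correlation between sample beta
profiles (pairwise-complete over missing values) with average linkage,
the conventional choice for methylation sample dendrograms.  Trees are
exportable as Newick plus a leaf-reordered matrix TSV for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError, ParameterError
from .io import BetaMatrix

__all__ = ["ClusterResult", "cluster_samples", "export_tree_and_heatmap"]


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples.

    ``linkage`` is the scipy linkage matrix (n-1 merges with heights),
    ``leaf_order`` the dendrogram leaf sequence, ``cophenetic`` the
    condensed cophenetic distance matrix, and ``two_cluster_labels`` the
    sample partition at the two-cluster cut.
    """

    sample_ids: tuple
    linkage: np.ndarray
    leaf_order: tuple
    cophenetic: np.ndarray
    two_cluster_labels: dict

    def cut_sets(self) -> tuple[frozenset, frozenset]:
        labels = set(self.two_cluster_labels.values())
        groups = [frozenset(s for s, l in self.two_cluster_labels.items() if l == lab)
                  for lab in sorted(labels)]
        while len(groups) < 2:
            groups.append(frozenset())
        return groups[0], groups[1]


def cluster_samples(beta: BetaMatrix, probes, distance: str = "correlation",
                    linkage: str = "average") -> ClusterResult:
    """Cluster samples over the given probe subset.

    ``distance`` is ``"correlation"`` (1 - Pearson, pairwise-complete)
    or ``"euclidean"`` (probes with any missing value dropped).
    Deterministic given the input order; scipy breaks merge ties by
    lowest cluster index.
    """
    probes = [p for p in probes]
    if not probes:
        raise InputError("probe subset must not be empty")
    missing = set(probes) - set(beta.probe_ids)
    if missing:
        raise InputError(f"probes not in matrix: {sorted(missing)[:5]}")
    sub = beta.data.loc[probes]
    if sub.shape[1] < 2:
        raise InputError("need at least 2 samples to cluster")

    if distance == "correlation":
        corr = sub.corr(method="pearson", min_periods=2)
        if corr.isna().to_numpy().any():
            raise InputError("correlation undefined for some sample pair (too much missingness)")
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    elif distance == "euclidean":
        complete = sub.dropna(axis=0)
        if complete.empty:
            raise InputError("no complete probes for euclidean distance")
        x = complete.to_numpy(dtype=float).T
        dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    else:
        raise ParameterError(f"unknown distance {distance!r}")

    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    coph = hierarchy.cophenet(Z)
    leaves = hierarchy.leaves_list(Z)
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    samples = tuple(sub.columns)
    return ClusterResult(
        sample_ids=samples,
        linkage=Z,
        leaf_order=tuple(samples[i] for i in leaves),
        cophenetic=coph,
        two_cluster_labels={s: int(c) for s, c in zip(samples, cut)},
    )


def _to_newick(Z: np.ndarray, labels) -> str:
    tree = hierarchy.to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def export_tree_and_heatmap(result: ClusterResult, beta: BetaMatrix, probes,
                            out_dir, image: bool = False) -> dict:
    """Write the dendrogram (Newick) and the leaf-reordered matrix TSV.

    Branch lengths are differences of merge heights, so leaf-to-root
    path lengths reproduce the linkage heights.  With ``image=True`` a
    PNG heatmap is rendered as well.
    """
    probes = [p for p in probes]
    if not probes:
        raise InputError("probe subset must not be empty")
    if set(result.sample_ids) != set(beta.sample_ids):
        raise InputError("cluster result and matrix describe different samples")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    newick_path = out_dir / "samples.nwk"
    newick_path.write_text(_to_newick(result.linkage, list(result.sample_ids)) + "\n")

    ordered = beta.data.loc[probes, list(result.leaf_order)]
    matrix_path = out_dir / "heatmap_matrix.tsv"
    ordered.to_csv(matrix_path, sep="\t", index_label="probe_id", float_format="%.6g")

    manifest = {"newick": str(newick_path), "heatmap_matrix": str(matrix_path)}
    if image:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 8))
        ax.imshow(ordered.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                  vmin=0.0, vmax=1.0, interpolation="nearest")
        ax.set_xticks(range(len(result.leaf_order)))
        ax.set_xticklabels(result.leaf_order, rotation=90, fontsize=6)
        ax.set_yticks([])
        ax.set_title("beta values (rows: signature CpGs)")
        png_path = out_dir / "heatmap.png"
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        manifest["heatmap_png"] = str(png_path)
    return manifest
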