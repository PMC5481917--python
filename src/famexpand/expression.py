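"""Expression divergence: Spearman distance + complete-linkage clustering.

Expression matrices are genes x tissues tables of nonnegative FPKM-like
abundances. The distance between two genes is ``1 - rho`` where rho is
the Spearman rank correlation of their tissue profiles (average ranks for
ties), so distances live in [0, 2] and are invariant to per-gene monotone
transforms of expression. Hierarchical clustering is agglomerative with
complete linkage (merge by maximum inter-cluster distance), cut at a
user-chosen number of clusters k; per-cluster tissue patterns are called
up/down/flat from the mean of row-wise z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: preset cluster counts mirroring the nine- and five-cluster analyses
K_PRESETS = {"brassica_rapa_like": 9, "brassica_oleracea_like": 5}


@dataclass
class ClusteringResult:
    distance: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix (merge list with heights)
    labels: pd.Series  # gene -> cluster index (0-based) for the given k
    k: int

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def load_matrix(path) -> pd.DataFrame:
    """Read an expression TSV (gene_id index + one column per tissue)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.columns.duplicated().any():
        raise ValueError(f"{path}: tissue labels must be unique")
    if (m.to_numpy() < 0).any():
        raise ValueError(f"{path}: expression values must be nonnegative")
    return m


def filter_expressed(
    matrix: pd.DataFrame, min_value: float = 0.0, min_tissues: int = 1
) -> pd.DataFrame:
    """Keep genes with expression > min_value in at least min_tissues tissues."""
    if min_tissues > matrix.shape[1]:
        raise ValueError(
            f"min_tissues={min_tissues} exceeds {matrix.shape[1]} tissues"
        )
    keep = (matrix > min_value).sum(axis=1) >= min_tissues
    out = matrix.loc[keep]
    logger.info("filter_expressed kept %d of %d genes", len(out), len(matrix))
    if out.empty:
        raise ValueError("no genes pass the expression filter")
    return out


def spearman_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between gene rows (average ranks for ties).

    Rows with zero rank variance (constant profiles) have undefined
    correlation; their off-diagonal distances are set to 1 with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two tissues")
    ranks = np.apply_along_axis(rankdata, 1, matrix.to_numpy(dtype=float))
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        logger.warning(
            "%d constant expression rows: distance fixed at 1", int(constant.sum())
        )
    safe = np.where(constant, 1.0, norms)
    rho = (centered @ centered.T) / np.outer(safe, safe)
    dist = 1.0 - rho
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    np.clip(dist, 0.0, 2.0, out=dist)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def complete_linkage(distance: pd.DataFrame, k: int) -> ClusteringResult:
    """Agglomerative complete-linkage clustering cut at k clusters.

    Labels are renumbered 0..k-1 in order of first appearance along the
    input gene order, making them deterministic and comparable across
    monotone-equivalent inputs.
    """
    n = len(distance)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    condensed = squareform(distance.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return ClusteringResult(
        distance=distance,
        linkage=Z,
        labels=pd.Series(labels, index=distance.index, name="cluster"),
        k=k,
    )


def call_patterns(
    matrix: pd.DataFrame, labels: pd.Series, z_threshold: float = 0.5
) -> pd.DataFrame:
    """Per-cluster per-tissue expression calls: up, down, or flat.

    Rows are z-scored gene-wise (constant rows are all-zero); the cluster
    mean z-score per tissue is compared against +/- z_threshold.
    """
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (values - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    zdf = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    rows = []
    for cluster, idx in labels.groupby(labels).groups.items():
        means = zdf.loc[idx].mean(axis=0)
        calls = {
            t: ("up" if m > z_threshold else "down" if m < -z_threshold else "flat")
            for t, m in means.items()
        }
        rows.append({"cluster": cluster, "n_genes": len(idx), **calls})
    return pd.DataFrame(rows).set_index("cluster").sort_index()


def plot_heatmap(matrix: pd.DataFrame, result: ClusteringResult, path) -> None:
    """Plain clustered heatmap (genes in dendrogram order) written to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = hierarchy.leaves_list(result.linkage)
    data = np.log1p(matrix.to_numpy(dtype=float))[order]
    fig, ax = plt.subplots(figsize=(6, max(4, len(matrix) * 0.02)))
    im = ax.imshow(data, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_ylabel(f"{len(matrix)} genes (dendrogram order)")
    fig.colorbar(im, ax=ax, label="log1p expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
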