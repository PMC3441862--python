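"""Two-way (genes x samples) unsupervised hierarchical clustering.

Distance is 1 - Pearson correlation between rows (genes) or columns
(samples); agglomeration is average linkage. Inputs are sorted
lexicographically by label before clustering so the result is invariant to
input order, and trees are exported as Newick with branch lengths equal to
merge-height differences. The sample tree cut at its root's two children
yields a two-cluster labelling whose purity against tumor/normal labels is
the separation check used for cohort-level validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class ClusterResult:
    sample_tree: str  # Newick
    gene_tree: str
    sample_order: list[str]
    gene_order: list[str]
    sample_linkage: np.ndarray
    gene_linkage: np.ndarray
    two_cluster_labels: pd.Series  # per-sample {"A", "B"}
    separation_purity: float  # NaN when no tissue labels given


def correlation_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between the rows of ``matrix``.

    Constant rows have undefined correlation; their distances are set to 1
    (uninformative) with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s): correlation "
                      "undefined, distance set to 1", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    # enforce exact symmetry against floating-point asymmetry
    return (dist + dist.T) / 2.0


def average_linkage(dist: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration of a square distance matrix."""
    condensed = squareform(dist, checks=False)
    return hierarchy.linkage(condensed, method="average")


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        left, right, height = (int(linkage[i - n, 0]), int(linkage[i - n, 1]),
                               float(linkage[i - n, 2]))
        ltxt, lh = node(left)
        rtxt, rh = node(right)
        return f"({ltxt}:{height - lh:.10g},{rtxt}:{height - rh:.10g})", height

    text, _ = node(2 * n - 2)
    return text + ";"


def two_cluster_labels(linkage: np.ndarray, labels: list[str]) -> pd.Series:
    """Cut the tree at the root's children into clusters 'A' and 'B'."""
    assignment = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    return pd.Series(np.where(assignment == assignment[0], "A", "B"),
                     index=labels)


def separation_purity(cluster_labels: pd.Series, tissue_labels: pd.Series) -> float:
    """Best-matching agreement between the 2-cut and tissue type, in [0.5, 1]."""
    tissue = tissue_labels.reindex(cluster_labels.index)
    a = (cluster_labels == "A").to_numpy()
    t = (tissue == tissue.iloc[0]).to_numpy()
    agree = (a == t).mean()
    return float(max(agree, 1.0 - agree))


def two_way_cluster(matrix: pd.DataFrame,
                    tissue_labels: pd.Series | None = None) -> ClusterResult:
    """Cluster genes (rows) and samples (columns) of an expression matrix.

    ``matrix``: genes x samples of expression log2 ratios; at least 2 of
    each. ``tissue_labels``, if given, maps sample -> {'T','N'} for the
    separation-purity check.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if matrix.isna().any().any():
        raise ValueError("missing values are not allowed")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    genes = matrix.index.tolist()
    samples = matrix.columns.tolist()

    gene_link = average_linkage(correlation_distance_matrix(matrix.to_numpy()))
    sample_link = average_linkage(correlation_distance_matrix(matrix.to_numpy().T))

    gene_order = [genes[i] for i in hierarchy.leaves_list(gene_link)]
    sample_order = [samples[i] for i in hierarchy.leaves_list(sample_link)]
    labels2 = two_cluster_labels(sample_link, samples)
    purity = (separation_purity(labels2, tissue_labels)
              if tissue_labels is not None else float("nan"))
    return ClusterResult(
        sample_tree=linkage_to_newick(sample_link, samples),
        gene_tree=linkage_to_newick(gene_link, genes),
        sample_order=sample_order, gene_order=gene_order,
        sample_linkage=sample_link, gene_linkage=gene_link,
        two_cluster_labels=labels2, separation_purity=purity)


def export_heatmap_inputs(result: ClusterResult, matrix: pd.DataFrame,
                          outdir: str) -> dict[str, str]:
    """Write the reordered matrix, both Newick trees and color-scale metadata.

    Returns the mapping of artifact name -> path; enough to regenerate a
    clustered-heatmap display downstream.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reordered = matrix.loc[result.gene_order, result.sample_order]
    paths = {
        "matrix": str(out / "clustered_matrix.tsv"),
        "sample_tree": str(out / "samples.nwk"),
        "gene_tree": str(out / "genes.nwk"),
        "scale": str(out / "color_scale.tsv"),
    }
    reordered.to_csv(paths["matrix"], sep="\t")
    Path(paths["sample_tree"]).write_text(result.sample_tree + "\n")
    Path(paths["gene_tree"]).write_text(result.gene_tree + "\n")
    lo, hi = float(np.nanmin(matrix.to_numpy())), float(np.nanmax(matrix.to_numpy()))
    pd.DataFrame({"min": [lo], "center": [0.0], "max": [hi]}).to_csv(
        paths["scale"], sep="\t", index=False)
    return paths
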