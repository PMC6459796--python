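"""k-means partitioning of genes into ordered occupancy classes.

Genes are clustered on their raw TSS-window bin profiles (no per-row
standardization — the classes are meant to order from high to low
modification level, which row scaling would destroy).  Labels are relabeled
1..k by descending cluster mean occupancy, so label 1 is always the most
heavily marked class and label k the unmarked background.

The partition is fit once (typically on the wild-type matrix) and applied
unchanged to other matrices over the same genes, so genotype metagenes are
compared over common gene groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from tssmeta.occupancy import OccupancyMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    """k-means settings: k classes, best of ``restarts`` k-means++ runs."""

    k: int = 4
    restarts: int = 10
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class ClusterAssignment:
    """Gene -> label map plus per-label centroids, labels ordered high -> low."""

    labels: dict[str, int]             # gene_name -> 1..k
    centroids: np.ndarray              # (k, B); row i is the centroid of label i+1
    mean_occupancy: np.ndarray         # (k,); mean of row means per label, descending
    inertia: float = field(default=float("nan"))

    @property
    def k(self) -> int:
        return len(self.mean_occupancy)

    def sizes(self) -> dict[int, int]:
        counts = {label: 0 for label in range(1, self.k + 1)}
        for label in self.labels.values():
            counts[label] += 1
        return counts

    def genes_in(self, label: int) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == label]


def kmeans_occupancy(matrix: OccupancyMatrix, cfg: ClusterConfig | None = None) -> ClusterAssignment:
    """Partition genes into k occupancy classes by Lloyd k-means.

    Standard squared-Euclidean k-means with k-means++ initialization, best of
    ``cfg.restarts`` runs by within-cluster sum of squares.  Rows are processed
    in gene_name-sorted order so the result is deterministic given the seed,
    regardless of input row order.  Raw labels are remapped to 1..k by
    descending cluster mean occupancy (mean over each cluster's row means).
    """
    if cfg is None:
        cfg = ClusterConfig()
    order = np.argsort(np.asarray(matrix.gene_names, dtype=object))
    names = [matrix.gene_names[i] for i in order]
    X = matrix.values[order]
    n_distinct = len(np.unique(X, axis=0))
    if cfg.k > n_distinct:
        raise ValueError(f"k={cfg.k} exceeds the {n_distinct} distinct profiles")

    km = KMeans(
        n_clusters=cfg.k,
        init="k-means++",
        n_init=cfg.restarts,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    ).fit(X)
    raw = km.labels_

    row_means = X.mean(axis=1)
    cluster_means = np.array([row_means[raw == c].mean() for c in range(cfg.k)])
    # relabel: highest-occupancy cluster becomes 1, lowest becomes k
    rank = np.argsort(-cluster_means)          # raw label order by descending mean
    new_of_raw = np.empty(cfg.k, dtype=int)
    new_of_raw[rank] = np.arange(1, cfg.k + 1)

    labels = {name: int(new_of_raw[c]) for name, c in zip(names, raw)}
    return ClusterAssignment(
        labels=labels,
        centroids=km.cluster_centers_[rank],
        mean_occupancy=cluster_means[rank],
        inertia=float(km.inertia_),
    )


def apply_assignment(
    assignment: ClusterAssignment, other_matrix: OccupancyMatrix
) -> dict[int, OccupancyMatrix]:
    """Group rows of another matrix by a fixed, previously fit partition.

    No re-clustering happens: the gene -> label map is applied as-is, so the
    same gene groups can be profiled in a second genotype.  Genes of
    ``other_matrix`` missing from the assignment raise an error naming them.
    """
    missing = [g for g in other_matrix.gene_names if g not in assignment.labels]
    if missing:
        raise KeyError(f"genes missing from assignment: {missing[:10]}")
    groups: dict[int, list[str]] = {label: [] for label in range(1, assignment.k + 1)}
    for gene in other_matrix.gene_names:
        groups[assignment.labels[gene]].append(gene)
    return {
        label: other_matrix.subset(genes)
        for label, genes in groups.items()
        if genes
    }


def read_assignment(source) -> ClusterAssignment:
    """Read a gene -> label TSV written by :func:`write_assignment`.

    Centroids and mean occupancies are not stored in the TSV; the returned
    assignment carries empty placeholders sized to k and supports grouping
    and distribution queries only.
    """
    import pandas as pd

    table = pd.read_csv(source, sep="\t")
    labels = {str(g): int(c) for g, c in zip(table["gene"], table["cluster"])}
    k = max(labels.values())
    return ClusterAssignment(
        labels=labels,
        centroids=np.empty((k, 0)),
        mean_occupancy=np.full(k, np.nan),
    )


def write_assignment(assignment: ClusterAssignment, handle) -> None:
    """Write the gene -> label map as 2-column TSV (gene_name, cluster_label)."""
    handle.write("gene\tcluster\n")
    for gene in sorted(assignment.labels):
        handle.write(f"{gene}\t{assignment.labels[gene]}\n")
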