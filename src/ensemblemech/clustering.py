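"""RMSD-threshold conformational clustering of a combined ensemble.

Implements the neighbor-count greedy rule (Daura/gromos style): repeatedly
take the frame with the most neighbors within the RMSD threshold, form a
cluster from it and its neighbors, remove them, and continue.  Clusters are
labeled by the provenance of their members (unbound-only / bound-only /
mixed), which is the diagnostic for conformational selection: mixed clusters
mean the unbound ensemble visits bound-like conformations at that
similarity threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import (
    AtomSelection,
    ConformationalEnsemble,
    concatenate,
)
from .superpose import pairwise_rmsd_matrix

__all__ = [
    "ClusterSet",
    "daura_cluster",
    "cluster_combined",
    "label_clusters",
    "threshold_sweep",
]


@dataclass
class ClusterSet:
    """Result of one RMSD-threshold clustering pass.

    ``assignments`` maps every frame to a cluster id (creation order);
    ``centers`` holds each cluster's representative frame index.  Populations
    are split by the provenance of the member frames; a singleton is a
    1-member cluster.
    """

    threshold: float
    assignments: np.ndarray
    centers: np.ndarray
    provenance_label: list[str] = field(default_factory=list)
    populations: pd.DataFrame | None = None
    n_singletons: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def mixed_population_fraction(self) -> float:
        """Fraction of all frames that live in mixed-provenance clusters."""
        if self.populations is None:
            raise ValueError("cluster set has no provenance populations")
        total = self.populations[["n_unbound", "n_bound"]].to_numpy().sum()
        mixed = self.populations.loc[
            [lbl == "mixed" for lbl in self.provenance_label],
            ["n_unbound", "n_bound"],
        ].to_numpy().sum()
        return float(mixed / total)


def daura_cluster(distance_matrix: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Neighbor-count greedy clustering of a symmetric distance matrix.

    Ties in the neighbor count are broken toward the lowest frame index.
    Returns member-index arrays in cluster-creation order (the founding
    frame first in each array).
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if np.max(np.abs(d - d.T)) > 1e-6:
        raise ValueError("distance matrix is not symmetric (max asymmetry > 1e-6)")
    n = d.shape[0]
    adj = d <= threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    clusters: list[np.ndarray] = []
    adj = adj.copy()
    while alive.any():
        counts = np.where(alive, (adj & alive[None, :]).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & alive)
        members = np.concatenate([[center], members])
        clusters.append(members)
        alive[members] = False
    return clusters


def label_clusters(
    clusters: list[np.ndarray],
    provenance: np.ndarray,
    threshold: float,
) -> ClusterSet:
    """Assemble a :class:`ClusterSet` with provenance labels and populations."""
    n = len(provenance)
    assignments = np.full(n, -1, dtype=int)
    labels: list[str] = []
    rows = []
    centers = []
    n_singletons = 0
    for cid, members in enumerate(clusters):
        assignments[members] = cid
        centers.append(int(members[0]))
        prov = provenance[members]
        n_unb = int(np.sum(prov == "unbound"))
        n_bnd = int(np.sum(prov == "bound"))
        if n_unb > 0 and n_bnd > 0:
            labels.append("mixed")
        elif n_unb > 0:
            labels.append("unbound_only")
        else:
            labels.append("bound_only")
        if len(members) == 1:
            n_singletons += 1
        rows.append({"cluster": cid, "n_unbound": n_unb, "n_bound": n_bnd})
    if np.any(assignments < 0):
        raise AssertionError("some frames were left unassigned")
    return ClusterSet(
        threshold=threshold,
        assignments=assignments,
        centers=np.asarray(centers),
        provenance_label=labels,
        populations=pd.DataFrame(rows),
        n_singletons=n_singletons,
    )


def cluster_combined(
    unbound: ConformationalEnsemble,
    bound: ConformationalEnsemble,
    selection: AtomSelection,
    threshold: float,
    prefit: bool = True,
    distance_matrix: np.ndarray | None = None,
) -> ClusterSet:
    """Cluster the concatenated unbound+bound ensemble at one RMSD threshold.

    The pairwise RMSD matrix is built with a per-pair superposition on the
    clustering selection (pass ``distance_matrix`` to reuse one across
    thresholds).
    """
    combined, provenance = concatenate(unbound, bound)
    if distance_matrix is None:
        distance_matrix = pairwise_rmsd_matrix(combined, selection, prefit=prefit)
    clusters = daura_cluster(distance_matrix, threshold)
    return label_clusters(clusters, provenance, threshold)


def threshold_sweep(
    unbound: ConformationalEnsemble,
    bound: ConformationalEnsemble,
    selection: AtomSelection,
    thresholds,
    prefit: bool = True,
    distance_matrix: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[ClusterSet]]:
    """Cluster at each threshold (one shared distance matrix) and tabulate.

    Returns a table with one row per threshold — cluster count, singleton
    count, and the population fractions living in unbound-only / bound-only
    / mixed clusters — together with the underlying cluster sets.
    """
    thresholds = [float(t) for t in thresholds]
    if len(thresholds) == 0:
        raise ValueError("need at least one threshold")
    if sorted(thresholds) != thresholds:
        warnings.warn("thresholds were not ascending; sorting them")
        thresholds = sorted(thresholds)
    combined, provenance = concatenate(unbound, bound)
    if distance_matrix is None:
        distance_matrix = pairwise_rmsd_matrix(combined, selection, prefit=prefit)
    rows = []
    sets: list[ClusterSet] = []
    n_total = combined.n_frames
    for thr in thresholds:
        cs = label_clusters(daura_cluster(distance_matrix, thr), provenance, thr)
        sets.append(cs)
        pops = cs.populations
        by_label = {"unbound_only": 0, "bound_only": 0, "mixed": 0}
        for lbl, row in zip(cs.provenance_label, pops.itertuples()):
            by_label[lbl] += row.n_unbound + row.n_bound
        rows.append(
            {
                "threshold": thr,
                "n_clusters": cs.n_clusters,
                "n_singletons": cs.n_singletons,
                "frac_unbound_only": by_label["unbound_only"] / n_total,
                "frac_bound_only": by_label["bound_only"] / n_total,
                "frac_mixed": by_label["mixed"] / n_total,
            }
        )
    return pd.DataFrame(rows), sets
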