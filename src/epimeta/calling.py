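"""From consensus scores to putative epitopes.

Two steps:

1. **Dynamic threshold.**  The number of residues called epitopal is
   N = round(6.1 * R**0.3), where R is the count of surface-exposed residues
   on the antigen; the N top-scoring residues form the predicted set.  N is
   deliberately generous relative to a single epitope's size, so the
   predicted set can span several spatial regions.

2. **Spatial partitioning.**  The predicted residues are clustered by
   agglomerative hierarchical clustering (Ward minimum-variance linkage on
   Euclidean distances between residue geometric centers).  The number of
   putative epitopes k is read off the dendrogram: for each candidate k, the
   gap is the vertical distance a horizontal line cutting exactly k branches
   can travel without crossing a merge; the k with the largest gap wins
   (ties go to the smaller k).  k=1 is not a candidate -- the rule needs at
   least one cut below the final merge, so a single spread-out epitope may be
   split in two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .structure import AntigenStructure, ResidueId, SurfaceProfile


@dataclass
class PredictionResult:
    antigen_id: str
    scores: np.ndarray            # consensus score per residue (file order)
    N: int                        # dynamic threshold
    top_indices: np.ndarray       # indices of the top-N residues, rank order

    @property
    def top_set(self) -> set[int]:
        return set(int(i) for i in self.top_indices)


@dataclass
class Dendrogram:
    """Merge records of an agglomerative clustering ((n-1) x 4 linkage matrix)."""

    merges: np.ndarray            # scipy linkage format: left, right, height, size
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusterSet:
    k: int
    labels: np.ndarray            # cluster id (1..k) per top-set residue
    members: list[list[int]]      # per cluster: indices into the top set
    gap_table: dict[int, float]   # candidate k -> vertical gap


def dynamic_threshold(R: int, coef: float = 6.1, exponent: float = 0.3,
                      rounding: str = "nearest") -> int:
    """Number of residues to call epitopal: N = round(coef * R**exponent).

    R is the antigen's surface-exposed residue count.  Rounding is
    half-up ("nearest", default), "floor" or "ceil".
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    x = coef * R ** exponent
    if rounding == "nearest":
        return int(np.floor(x + 0.5))
    if rounding == "floor":
        return int(np.floor(x))
    if rounding == "ceil":
        return int(np.ceil(x))
    raise ValueError(f"unknown rounding mode {rounding!r}")


def select_top_n(scores: np.ndarray, N: int) -> np.ndarray:
    """Indices of the N highest-scoring residues, in rank order.

    Boundary ties are broken by residue (file) order -- earlier residue wins
    -- so the selection is deterministic.  If N exceeds the number of scored
    residues, all are returned.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if N < 1:
        raise ValueError("N must be >= 1")
    order = np.argsort(-scores, kind="stable")  # stable: ties keep file order
    return order[: min(N, scores.size)]


def ward_cluster(centers: np.ndarray) -> Dendrogram:
    """Ward-linkage agglomerative clustering of residue geometric centers.

    Euclidean metric, no distance threshold.  With fewer than two points the
    result is a degenerate dendrogram with no merges.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    n = len(centers)
    if n < 2:
        return Dendrogram(np.empty((0, 4)), n_leaves=n)
    return Dendrogram(linkage(centers, method="ward"), n_leaves=n)


def optimal_cluster_count(dendrogram: Dendrogram, k_max: int = 8) -> tuple[int, dict[int, float]]:
    """Pick k by the maximum-vertical-gap rule.

    A horizontal line cutting the dendrogram between merge heights h(n-k) and
    h(n-k+1) crosses exactly k branches, so
    ``gap(k) = h(n-k+1) - h(n-k)`` (1-based merge index) is the vertical
    distance such a line can travel.  Candidates are k = 2..min(k_max, n-1);
    ties break toward the smaller k.
    """
    n = dendrogram.n_leaves
    if n < 2:
        raise ValueError("need at least two leaves")
    h = dendrogram.heights  # h[m-1] is the height of the m-th merge
    gaps: dict[int, float] = {}
    for k in range(2, min(k_max, n - 1) + 1):
        gaps[k] = float(h[n - k] - h[n - k - 1])
    if not gaps:  # n == 2: the only possible partition
        return 2, {2: float(h[0])}
    best = min(gaps, key=lambda k: (-gaps[k], k))
    return best, gaps


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels (1..k) per leaf for a k-cluster cut."""
    if dendrogram.n_leaves < 2:
        return np.ones(dendrogram.n_leaves, dtype=int)
    return fcluster(dendrogram.merges, t=k, criterion="maxclust")


def call_epitopes(
    structure: AntigenStructure,
    profile: SurfaceProfile,
    scores: np.ndarray,
    k_max: int = 8,
    antigen_id: str = "antigen",
) -> tuple[PredictionResult, ClusterSet, Dendrogram]:
    """Full calling pipeline: threshold, top-N selection, spatial partition."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(structure):
        raise ValueError("scores and structure describe different residue sets")
    N = dynamic_threshold(profile.R)
    top = select_top_n(scores, N)
    prediction = PredictionResult(antigen_id, scores, N, top)

    centers = structure.centers[top]
    dendro = ward_cluster(centers)
    if dendro.n_leaves < 2:
        labels = np.ones(len(top), dtype=int)
        clusters = ClusterSet(1, labels, [list(range(len(top)))], {})
        return prediction, clusters, dendro
    k, gaps = optimal_cluster_count(dendro, k_max=k_max)
    labels = cut_dendrogram(dendro, k)
    members = [list(np.flatnonzero(labels == c)) for c in range(1, k + 1)]
    return prediction, ClusterSet(k, labels, members, gaps), dendro


def cluster_residues(structure: AntigenStructure, prediction: PredictionResult,
                     clusters: ClusterSet) -> list[list[ResidueId]]:
    """Per-cluster residue identifier lists (clusters indexed 1..k)."""
    return [[structure.residues[prediction.top_indices[i]] for i in cluster]
            for cluster in clusters.members]


def prediction_table(structure: AntigenStructure, prediction: PredictionResult,
                     clusters: ClusterSet | None = None) -> pd.DataFrame:
    """Per-residue output: consensus score, top-N membership, cluster id."""
    n = len(structure)
    in_top = np.zeros(n, dtype=int)
    in_top[prediction.top_indices] = 1
    cluster_id = np.zeros(n, dtype=int)
    if clusters is not None:
        for pos, lab in zip(prediction.top_indices, clusters.labels):
            cluster_id[pos] = lab
    return pd.DataFrame({
        "chain": [r.chain for r in structure.residues],
        "seqnum": [r.seqnum for r in structure.residues],
        "icode": [r.icode for r in structure.residues],
        "consensus_score": prediction.scores,
        "in_top_n": in_top,
        "cluster_id": cluster_id,
    })
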