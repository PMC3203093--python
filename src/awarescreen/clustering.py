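"""Two-group k-medoids (PAM) partitioning of respondents.

Respondents are split into two subsets by exact Partitioning Around
Medoids on the scale's own items, Euclidean distance on raw responses.
The partition supplies the grouping factor for the per-item variance
decomposition.  Exact PAM (BUILD + SWAP) is used rather than a
subsampled large-data variant: at a few hundred respondents the full
algorithm is cheap, and subsampled k-medoids converges to it as the
subsample grows.  All tie-breaks go to the lowest row index, so the
algorithm is fully deterministic; the ``seed`` argument is accepted for
interface stability but no randomness is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateDataError

__all__ = ["ClusterAssignment", "pam_two_cluster"]


@dataclass(frozen=True)
class ClusterAssignment:
    """A two-cluster partition: 0/1 labels, medoid row indices, sizes."""

    labels: np.ndarray
    medoid_indices: tuple
    cluster_sizes: tuple

    def swapped(self) -> "ClusterAssignment":
        """The same partition with labels 0 and 1 exchanged."""
        return ClusterAssignment(
            labels=1 - self.labels,
            medoid_indices=(self.medoid_indices[1], self.medoid_indices[0]),
            cluster_sizes=(self.cluster_sizes[1], self.cluster_sizes[0]),
        )


def _pam_medoids(dist: np.ndarray) -> tuple[int, int]:
    """Exact PAM for k=2 on a precomputed distance matrix."""
    n = dist.shape[0]
    # BUILD: first medoid minimises total distance, second minimises the
    # total distance to the nearer of the two medoids.
    m1 = int(np.argmin(dist.sum(axis=1)))
    costs = np.minimum(dist, dist[:, m1][:, None]).sum(axis=0)
    costs[m1] = np.inf
    m2 = int(np.argmin(costs))
    current = float(np.minimum(dist[:, m1], dist[:, m2]).sum())
    # SWAP: try replacing either medoid by any non-medoid until no swap
    # strictly lowers the total cost.
    for _ in range(n):  # cost strictly decreases; n iterations is a safe cap
        cost_rep1 = np.minimum(dist, dist[:, m2][:, None]).sum(axis=0)  # m1 -> h
        cost_rep2 = np.minimum(dist, dist[:, m1][:, None]).sum(axis=0)  # m2 -> h
        cost_rep1[[m1, m2]] = np.inf
        cost_rep2[[m1, m2]] = np.inf
        h1, h2 = int(np.argmin(cost_rep1)), int(np.argmin(cost_rep2))
        best1, best2 = cost_rep1[h1], cost_rep2[h2]
        best = min(best1, best2)
        if not best < current - 1e-12:
            break
        if best1 <= best2:  # prefer replacing the first medoid on ties
            m1 = h1
        else:
            m2 = h2
        current = best
    return (m1, m2) if m1 < m2 else (m2, m1)


def pam_two_cluster(values: np.ndarray, seed: int = 0) -> ClusterAssignment:
    """Partition rows of ``values`` into two clusters around medoids.

    Parameters
    ----------
    values : (n, q) array
        Complete-case response rows; no NaN allowed.
    seed : int
        Unused (the algorithm is deterministic); kept so the clustering
        step has the same call signature as stochastic alternatives.

    Raises
    ------
    DegenerateDataError
        If all rows are identical (no meaningful partition exists).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D")
    n = values.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects to cluster, got {n}")
    if np.isnan(values).any():
        raise ValueError("values must not contain missing entries")
    dist = cdist(values, values)
    if not dist.max() > 0.0:
        raise DegenerateDataError("all respondent rows identical; cannot partition")
    m1, m2 = _pam_medoids(dist)
    # assign to the nearer medoid; ties go to the first medoid, except
    # that each medoid always belongs to its own cluster
    labels = (dist[:, m2] < dist[:, m1]).astype(np.int8)
    labels[m1], labels[m2] = 0, 1
    sizes = (int(n - labels.sum()), int(labels.sum()))
    if min(sizes) == 0:
        raise DegenerateDataError("a cluster came out empty; data too degenerate")
    return ClusterAssignment(labels=labels, medoid_indices=(m1, m2), cluster_sizes=sizes)
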