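"""Consolidation of filtered candidates into final predicted metal sites.

High-confidence candidates are grouped with DBSCAN (Euclidean metric,
eps = 5 A, min_samples = 2 by default: a cluster needs at least two candidate
positions within the radius, since sampled metal locations are sparse).
Isolated candidates are noise and are discarded from the prediction.  Each
cluster is reported as a single site at the unweighted arithmetic mean of its
members' coordinates; a confidence-weighted mean is available behind a flag.

Cluster ids are canonicalized by smallest member index, which makes the
labeling independent of input order up to the DBSCAN border-point convention
(border points join the first core cluster reached in index order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .errors import DomainError

CLUSTER_EPS_DEFAULT = 5.0
CLUSTER_MIN_SAMPLES_DEFAULT = 2


@dataclass(frozen=True)
class ClusterResult:
    """DBSCAN assignment plus per-cluster centroids and member lists."""

    assignments: np.ndarray  # (n,) cluster id, -1 for noise
    centroids: np.ndarray  # (k, 3)
    members: tuple[tuple[int, ...], ...]  # per-cluster candidate indices

    @property
    def n_clusters(self) -> int:
        return int(self.centroids.shape[0])


def cluster_candidates(
    positions: np.ndarray,
    eps: float = CLUSTER_EPS_DEFAULT,
    min_samples: int = CLUSTER_MIN_SAMPLES_DEFAULT,
    weights: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster candidate positions; empty input yields an empty result.

    Parameters
    ----------
    weights
        Optional per-candidate weights for the centroid average (confidence
        weighting); the unweighted mean is the default.
    """
    if eps <= 0:
        raise DomainError(f"eps must be positive, got {eps}")
    if min_samples < 1:
        raise DomainError(f"min_samples must be >= 1, got {min_samples}")
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = positions.shape[0]
    if n == 0:
        return ClusterResult(
            assignments=np.zeros(0, dtype=int),
            centroids=np.zeros((0, 3)),
            members=(),
        )
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(positions)
    # canonicalize ids by smallest member index
    assignments = np.full(n, -1, dtype=int)
    members: list[tuple[int, ...]] = []
    centroids: list[np.ndarray] = []
    seen: dict[int, int] = {}
    for i in range(n):
        lab = int(raw[i])
        if lab == -1:
            continue
        if lab not in seen:
            seen[lab] = len(members)
            idx = np.where(raw == lab)[0]
            members.append(tuple(int(j) for j in idx))
            if weights is not None:
                w = np.asarray(weights, dtype=float)[idx]
                centroids.append((positions[idx] * w[:, None]).sum(0) / w.sum())
            else:
                centroids.append(positions[idx].mean(axis=0))
        assignments[i] = seen[lab]
    return ClusterResult(
        assignments=assignments,
        centroids=np.array(centroids) if centroids else np.zeros((0, 3)),
        members=tuple(members),
    )
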