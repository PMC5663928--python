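"""Radius-driven k-means conformational clustering under RMSD distance.

The cluster count is not chosen up front: after each converged k-means
pass, every cluster still violating the fixed RMSD radius (default 1.6 A)
is split — widest first — by seeding a new centroid at its farthest
member, and the pass repeats until all structures lie within the radius of
their centroid.
Initialisation is deterministic (first structure, then farthest-point), so
identical input and seed give identical models.  Structures are either
pre-aligned to a common reference once ("global", the default) or
re-superposed onto each centroid per distance evaluation ("pairwise").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import constants
from .metrics import apply_transform, superpose

__all__ = ["ClusterModel", "kmeans_rmsd", "population_report"]


@dataclass
class ClusterModel:
    n_structures: int
    assignments: np.ndarray  # cluster index per structure
    centroids: np.ndarray  # (k, n_atoms, 3)
    rmsd_to_centroid: np.ndarray  # per structure, A
    radius_threshold: float
    populations: np.ndarray  # fraction per cluster, sums to 1
    seed: int
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def _pairwise_rmsd_matrix(
    structures: np.ndarray, centroids: np.ndarray, pairwise: bool
) -> np.ndarray:
    """(n, k) RMSD of every structure to every centroid."""
    from scipy.spatial.distance import cdist

    n, atoms, _ = structures.shape
    k = centroids.shape[0]
    if not pairwise:
        flat_s = structures.reshape(n, atoms * 3)
        flat_c = centroids.reshape(k, atoms * 3)
        return cdist(flat_s, flat_c) / np.sqrt(atoms)
    out = np.empty((n, k))
    for i in range(n):
        for c in range(k):
            fit = superpose(structures[i], centroids[c])
            moved = apply_transform(structures[i], fit)
            out[i, c] = np.sqrt(np.mean(np.sum((moved - centroids[c]) ** 2, axis=1)))
    return out


def kmeans_rmsd(
    structures: np.ndarray,
    radius_threshold: float = constants.CLUSTER_RADIUS_A,
    seed: int = 0,
    align: str = "global",
    max_iter: int = 100,
) -> ClusterModel:
    """Cluster conformations until the radius guarantee holds.

    ``structures`` is (n, n_atoms, 3).  With ``align="global"`` every
    structure is first superposed onto the first structure and distances are
    then plain (Euclidean-form) RMSDs; ``align="pairwise"`` re-superposes
    per distance evaluation.  Assignment ties break to the lowest cluster
    index.  The returned model satisfies
    ``max(rmsd_to_centroid) <= radius_threshold`` (asserted) unless the
    iteration cap was hit, in which case ``converged`` is False.
    """
    structures = np.asarray(structures, dtype=float)
    if structures.ndim != 3 or structures.shape[2] != 3:
        raise ValueError("structures must have shape (n, n_atoms, 3)")
    n = structures.shape[0]
    if n < 1:
        raise ValueError("need at least 1 structure")
    if radius_threshold <= 0:
        raise ValueError("radius_threshold must be positive")
    if align not in ("global", "pairwise"):
        raise ValueError("align must be 'global' or 'pairwise'")
    pairwise = align == "pairwise"
    if not pairwise:
        aligned = np.empty_like(structures)
        ref = structures[0]
        for i in range(n):
            fit = superpose(structures[i], ref)
            aligned[i] = apply_transform(structures[i], fit)
        structures = aligned

    centroids = structures[[0]].copy()
    assignments = np.zeros(n, dtype=int)
    converged = True
    while True:
        # Lloyd iterations at fixed k until the assignment fixpoint
        for _ in range(max_iter):
            dist = _pairwise_rmsd_matrix(structures, centroids, pairwise)
            new_assign = np.argmin(dist, axis=1)  # argmin ties -> lowest index
            new_centroids = centroids.copy()
            for c in range(centroids.shape[0]):
                members = np.flatnonzero(new_assign == c)
                if members.size:
                    mean = structures[members].mean(axis=0)
                    if pairwise:
                        # re-superpose the mean onto the previous centroid to
                        # keep the representative frame stable
                        fit = superpose(mean, centroids[c])
                        mean = apply_transform(mean, fit)
                    new_centroids[c] = mean
            if np.array_equal(new_assign, assignments) and np.allclose(
                new_centroids, centroids
            ):
                break
            assignments = new_assign
            centroids = new_centroids
        else:
            converged = False
        dist = _pairwise_rmsd_matrix(structures, centroids, pairwise)
        to_own = dist[np.arange(n), assignments]
        if to_own.max() <= radius_threshold or centroids.shape[0] >= n:
            break
        # split every cluster violating the radius, widest first: each gets
        # a new centroid seeded at its farthest member
        order = np.argsort(
            [-to_own[assignments == c].max() if (assignments == c).any() else 0.0
             for c in range(centroids.shape[0])]
        )
        new_seeds = []
        for c in order:
            members = np.flatnonzero(assignments == c)
            if members.size == 0:
                continue
            worst = members[int(to_own[members].argmax())]
            if to_own[worst] > radius_threshold:
                new_seeds.append(structures[worst])
        centroids = np.concatenate([centroids, np.array(new_seeds)], axis=0)

    populations = np.bincount(assignments, minlength=centroids.shape[0]) / n
    model = ClusterModel(
        n_structures=n,
        assignments=assignments,
        centroids=centroids,
        rmsd_to_centroid=to_own,
        radius_threshold=radius_threshold,
        populations=populations,
        seed=seed,
        converged=converged,
    )
    if converged:
        assert model.rmsd_to_centroid.max() <= radius_threshold + 1e-12
    return model


def population_report(model: ClusterModel) -> List[dict]:
    """Clusters ranked by population (descending, ties by cluster index).

    Each row carries the centroid-nearest member as the representative
    structure reference.
    """
    rows = []
    order = sorted(
        range(model.n_clusters), key=lambda c: (-model.populations[c], c)
    )
    for rank, c in enumerate(order, start=1):
        members = np.flatnonzero(model.assignments == c)
        if members.size:
            rep = int(members[np.argmin(model.rmsd_to_centroid[members])])
        else:
            rep = -1
        rows.append(
            {
                "rank": rank,
                "cluster": c,
                "population": float(model.populations[c]),
                "n_members": int(members.size),
                "representative": rep,
            }
        )
    return rows
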