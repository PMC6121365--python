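"""Stage 1a: partition SNPs into k groups by mutual information.

The procedure is a k-medoids-style alternation specialised to genotype
data: k SNPs serve as cluster centroids, every SNP joins the centroid
with which it shares the most mutual information, and each cluster then
promotes to centroid the member whose summed MI against its cluster
(sMI) is maximal.  Assignment and update alternate until the centroid
set is stable or ``max_reps`` is reached.

SNPs with high mutual associativity end up in one group, so the
downstream pair screen only has to look inside clusters — for M SNPs in
k equal groups this cuts the pair search space by roughly a factor of k.

MI values against centroids are cached per centroid, and per-cluster MI
sub-matrices are updated incrementally as members migrate, so a full
M x M MI matrix is never materialised.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype import GenotypeMatrix
from .infotheory import mi_against, mi_cross

__all__ = ["ClusterState", "initialize_centroids", "assign_snps", "update_centroids", "cluster"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterState:
    """Partition of SNP indices into k clusters with one centroid each.

    ``assignment`` holds a cluster label per SNP (-1 before the first
    assignment pass); ``centroids[m]`` is the SNP index serving as the
    centroid of cluster ``m``.
    """

    k: int
    centroids: np.ndarray
    assignment: np.ndarray
    iteration: int = 0
    converged: bool = False
    _mi_cache: dict = field(default_factory=dict, repr=False)

    def members(self, m: int) -> np.ndarray:
        return np.where(self.assignment == m)[0]

    def check_partition(self, n_snps: int) -> None:
        if self.assignment.shape != (n_snps,):
            raise ValueError("assignment length must equal the number of SNPs")
        if (self.assignment < 0).any() or (self.assignment >= self.k).any():
            raise ValueError("assignment labels must be in [0, k)")
        for m, c in enumerate(self.centroids):
            if self.assignment[c] != m:
                raise ValueError(f"centroid {c} is not assigned to its own cluster {m}")


def initialize_centroids(g: GenotypeMatrix, k: int, seed) -> ClusterState:
    """Draw k distinct SNPs uniformly at random as initial centroids."""
    if not 1 <= k <= g.n_snps:
        raise ValueError(f"need 1 <= k <= M, got k={k}, M={g.n_snps}")
    rng = np.random.default_rng(seed)
    centroids = rng.choice(g.n_snps, size=k, replace=False)
    assignment = np.full(g.n_snps, -1, dtype=np.int64)
    return ClusterState(k=k, centroids=centroids, assignment=assignment)


def _centroid_mi(g: GenotypeMatrix, state: ClusterState) -> np.ndarray:
    """(M, k) MI of every SNP against the current centroids, cached per
    centroid SNP so re-used centroids cost nothing across repetitions."""
    cache = state._mi_cache
    missing = [int(c) for c in state.centroids if int(c) not in cache]
    if missing:
        fresh = mi_against(g, missing)
        for pos, c in enumerate(missing):
            cache[c] = fresh[:, pos]
    return np.column_stack([cache[int(c)] for c in state.centroids])


def assign_snps(g: GenotypeMatrix, state: ClusterState) -> ClusterState:
    """Assign every SNP to the centroid maximising MI(Si, Cm); ties go to
    the lowest cluster index, and centroids stay in their own cluster."""
    mi = _centroid_mi(g, state)
    state.assignment = np.argmax(mi, axis=1).astype(np.int64)  # argmax: first max wins ties
    state.assignment[state.centroids] = np.arange(state.k)
    return state


def update_centroids(
    g: GenotypeMatrix, state: ClusterState, rng: np.random.Generator | None = None
) -> ClusterState:
    """Promote, in each cluster, the member with maximal summed MI (sMI)
    to centroid.

    The member Sr maximising sMI satisfies sMI(Cm)/sMI(Sr) <= 1 against
    the current centroid, so the update is the deterministic reading of
    the renewal rule; ties break to the lowest SNP index.  An empty
    cluster is re-seeded with a random non-centroid SNP.
    """
    if rng is None:
        rng = np.random.default_rng()
    new_centroids = state.centroids.copy()
    for m in range(state.k):
        members = state.members(m)
        if members.size == 0:
            pool = np.setdiff1d(np.arange(g.n_snps), new_centroids)
            new_centroids[m] = rng.choice(pool)
            logger.info("cluster %d empty; re-seeded centroid at SNP %d", m, new_centroids[m])
            continue
        if members.size == 1:
            new_centroids[m] = members[0]
            continue
        smi = _cluster_smi(g, state, m, members)
        new_centroids[m] = members[int(np.argmax(smi))]  # first max: lowest index
    state.centroids = new_centroids
    return state


def _cluster_smi(
    g: GenotypeMatrix, state: ClusterState, m: int, members: np.ndarray
) -> np.ndarray:
    """sMI of every member of cluster ``m``: row sums of the within-
    cluster MI matrix (self-MI included, as each member belongs to its
    own sum).  The matrix is cached per cluster and patched row/column-
    wise for members that joined or left since the previous repetition.
    """
    key = ("cluster_mi", m)
    cached = state._mi_cache.get(key)
    if cached is not None:
        old_members, old_mat = cached
        common = np.intersect1d(old_members, members)
        if common.size and common.size >= members.size // 2:
            new = np.setdiff1d(members, common)
            pos_old = np.searchsorted(old_members, common)
            mat = np.empty((members.size, members.size))
            pos_common = np.searchsorted(members, common)
            pos_new = np.searchsorted(members, new)
            mat[np.ix_(pos_common, pos_common)] = old_mat[np.ix_(pos_old, pos_old)]
            if new.size:
                cross = mi_cross(g, new, members)
                mat[np.ix_(pos_new, np.arange(members.size))] = cross
                mat[np.ix_(np.arange(members.size), pos_new)] = cross.T
            state._mi_cache[key] = (members, mat)
            return mat.sum(axis=1)
    from .infotheory import mi_matrix

    mat = mi_matrix(g, members)
    state._mi_cache[key] = (members, mat)
    return mat.sum(axis=1)


def cluster(g: GenotypeMatrix, k: int, seed, max_reps: int = 50) -> ClusterState:
    """Full clustering loop: alternate assignment and centroid update
    until the centroid set stops changing or ``max_reps`` repetitions."""
    rng = np.random.default_rng(seed)
    state = initialize_centroids(g, k, rng)
    for rep in range(1, max_reps + 1):
        previous = set(state.centroids.tolist())
        assign_snps(g, state)
        update_centroids(g, state, rng)
        state.iteration = rep
        if set(state.centroids.tolist()) == previous:
            state.converged = True
            break
    # final assignment so every centroid owns its cluster
    assign_snps(g, state)
    logger.info(
        "clustering finished after %d repetitions (converged=%s); sizes=%s",
        state.iteration, state.converged,
        np.bincount(state.assignment, minlength=k).tolist(),
    )
    return state
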