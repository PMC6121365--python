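"""Stage 2, large candidate sets: improved ant-colony search.

The search space is the candidate set W of screened two-locus
combinations.  Each combination carries a pheromone value, initially
equal for all ("treated with equal possibility").  Per iteration every
ant picks ceil(K/2) combinations — with probability q0 by a pheromone-
weighted roulette, otherwise uniformly — merges them into a K-locus set,
and scores it with the K-locus chi-square.  Scored fitness is deposited
back onto the combinations the ant chose, after evaporation at rate rho.

The "improved" part is a memory archive: the best distinct loci sets
seen in any iteration are retained, and after the loop each archived set
is re-tested and reported when it beats the Bonferroni-corrected level.
Archive members do not deposit extra pheromone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import ceil

import numpy as np

from .genotype import GenotypeMatrix
from .infotheory import batch_chi2, bonferroni_threshold
from .screening import CandidateSet
from .search_exhaustive import InteractionResult, _make_results

__all__ = ["AcoConfig", "AcoState", "select_pair", "merge_and_score", "update_pheromone", "run_aco"]


@dataclass
class AcoConfig:
    """Tuning knobs of the ant-colony search.

    Defaults follow the package's simulation-mode settings: initial
    pheromone 100, exploitation threshold q0 = 0.6, evaporation
    rho = 0.05 (use ~0.01 on large real candidate sets), ant count
    scaled to |W| within [500, 5000], and 0.1 * |W| iterations.
    """

    gamma0: float = 100.0
    q0: float = 0.6
    rho: float = 0.05
    n_ants: int | None = None
    max_iter: int | None = None
    alpha_w: float = 1.0
    beta_w: float = 1.0
    eta: float = 1.0
    archive_size: int = 100
    seed: int | None = None

    def resolve(self, n_candidates: int) -> tuple[int, int]:
        """Concrete (n_ants, max_iter) for a candidate set of given size."""
        n = self.n_ants
        if n is None:
            n = int(np.clip(n_candidates // 10, 500, 5000))
        n = max(1, min(n, n_candidates - 1))
        it = self.max_iter
        if it is None:
            it = max(1, round(0.1 * n_candidates))
        return n, it


@dataclass
class AcoState:
    """Mutable search state: per-combination pheromone and the archive of
    the best loci sets (descending chi-square)."""

    pheromone: np.ndarray
    iteration: int = 0
    archive: dict = field(default_factory=dict)  # loci tuple -> chi2
    trace: list = field(default_factory=list)    # (iteration, best chi2, archive size)

    def archive_put(self, loci: tuple[int, ...], chi2: float, capacity: int) -> None:
        best = self.archive.get(loci)
        if best is None or chi2 > best:
            self.archive[loci] = chi2
        if len(self.archive) > capacity:
            cut = sorted(self.archive.items(), key=lambda kv: (-kv[1], kv[0]))[:capacity]
            self.archive = dict(cut)


def select_pair(
    state: AcoState,
    ant_available: np.ndarray,
    rng: np.random.Generator,
    q0: float = 0.6,
    alpha_w: float = 1.0,
    beta_w: float = 1.0,
    eta: float = 1.0,
) -> int:
    """Pick one combination index from the ant's unselected set.

    With probability q0 the pick is the pheromone-weighted roulette
    (weights gamma^alpha_w * eta^beta_w); otherwise it is uniform.
    """
    if len(ant_available) == 0:
        raise ValueError("ant has no combinations left to select")
    q = rng.uniform()
    if q <= q0:
        weights = state.pheromone[ant_available] ** alpha_w * eta**beta_w
        total = weights.sum()
        if total <= 0:
            choice = rng.integers(len(ant_available))
        else:
            choice = rng.choice(len(ant_available), p=weights / total)
    else:
        choice = rng.integers(len(ant_available))
    return int(ant_available[choice])


def merge_and_score(
    g: GenotypeMatrix, pair_a, pair_b, K: int = 3
) -> tuple[tuple[int, ...], float]:
    """Merge two combinations into a K-locus set and score it.

    If the union exceeds K loci, every K-subset is scored and the best
    is returned, so disjoint picks still yield a productive ant.
    """
    union = sorted(set(pair_a) | set(pair_b))
    if len(union) < K:
        raise ValueError("merged pairs span fewer than K loci")
    if len(union) == K:
        subsets = np.array([union], dtype=np.intp)
    else:
        subsets = np.array(list(combinations(union, K)), dtype=np.intp)
    stats, _ = batch_chi2(g, subsets)
    best = int(np.argmax(stats))
    return tuple(int(x) for x in subsets[best]), float(stats[best])


def update_pheromone(
    state: AcoState, selections, fitnesses, rho: float
) -> AcoState:
    """Evaporate then deposit: gamma <- (1 - rho) * gamma + sum of the
    chi-square fitness of every ant that selected each combination."""
    delta = np.zeros_like(state.pheromone)
    for chosen, fit in zip(selections, fitnesses):
        for idx in chosen:
            delta[idx] += fit
    state.pheromone = (1.0 - rho) * state.pheromone + delta
    return state


def run_aco(
    g: GenotypeMatrix,
    w: CandidateSet,
    K: int = 3,
    cfg: AcoConfig | None = None,
    alpha0: float = 0.05,
    correction_M: str = "total_snps",
) -> list[InteractionResult]:
    """Full improved-ACO search over the candidate set W.

    After ``max_iter`` iterations of select/merge/score/deposit, every
    archived loci set is re-tested with the K-locus chi-square and the
    ones below the Bonferroni-corrected level are returned sorted by
    p-value.  Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or AcoConfig()
    n_cand = len(w)
    if n_cand < 2:
        raise ValueError("ACO search needs at least two candidate combinations")
    n_ants, max_iter = cfg.resolve(n_cand)
    rng = np.random.default_rng(cfg.seed)
    state = AcoState(pheromone=np.full(n_cand, cfg.gamma0, dtype=np.float64))
    picks_per_ant = max(2, ceil(K / 2))
    pair_sets = [tuple(int(x) for x in row) for row in w.pairs]

    for t in range(1, max_iter + 1):
        state.iteration = t
        selections: list[list[int]] = []
        merged: list[tuple[int, ...]] = []
        for _ in range(n_ants):
            available = np.arange(n_cand)
            chosen: list[int] = []
            loci: set[int] = set()
            for _ in range(picks_per_ant):
                idx = select_pair(
                    state, available, rng, q0=cfg.q0,
                    alpha_w=cfg.alpha_w, beta_w=cfg.beta_w, eta=cfg.eta,
                )
                chosen.append(idx)
                loci.update(pair_sets[idx])
                available = available[available != idx]
            while len(loci) < K:  # identical loci despite distinct picks
                idx = int(rng.integers(n_cand))
                chosen.append(idx)
                loci.update(pair_sets[idx])
            selections.append(chosen)
            merged.append(tuple(sorted(loci)))

        fitnesses = _score_merged(g, state, merged, K, cfg.archive_size)
        update_pheromone(state, selections, fitnesses, cfg.rho)
        best = max(state.archive.values()) if state.archive else 0.0
        state.trace.append((t, best, len(state.archive)))

    archived = sorted(state.archive, key=lambda s: (-state.archive[s], s))
    combos = np.array(archived, dtype=np.intp)
    m_star = g.n_snps if correction_M == "total_snps" else len(np.unique(w.pairs))
    alpha = bonferroni_threshold(alpha0, m_star, K)
    stats, pvals = batch_chi2(g, combos)
    results = _make_results(combos, stats, pvals, 3**K - 1, alpha)
    return [r for r in results if r.significant]


def _score_merged(
    g: GenotypeMatrix, state: AcoState, merged, K: int, capacity: int
) -> np.ndarray:
    """Fitness of each ant's merged loci set: the best chi-square over
    its K-subsets; all scored subsets feed the archive."""
    all_subsets = []
    owners = []
    for a, loci in enumerate(merged):
        subs = [loci] if len(loci) == K else list(combinations(loci, K))
        all_subsets.extend(subs)
        owners.extend([a] * len(subs))
    combos = np.array(all_subsets, dtype=np.intp)
    stats, _ = batch_chi2(g, combos)
    fitness = np.zeros(len(merged))
    for sub, owner, stat in zip(all_subsets, owners, stats):
        fitness[owner] = max(fitness[owner], stat)
        state.archive_put(tuple(sub), float(stat), capacity)
    return fitness
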