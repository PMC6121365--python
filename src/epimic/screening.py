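"""Stage 1b: conditional-MI screening of within-cluster SNP pairs.

Every pair of SNPs that shares a cluster is scored with the case-stratum
(conditional) mutual information; pairs with cMI > tau enter the
candidate set W for the stage-2 search.  Pairs that straddle two
clusters are never tested — that restriction is the method's complexity
reduction.  On real data a pairwise chi-square p-value co-filter can be
enabled on top of the cMI rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .clustering import ClusterState
from .genotype import GenotypeMatrix
from .infotheory import batch_chi2, mi_matrix

__all__ = [
    "CandidateSet",
    "screen_pairs",
    "candidate_snp_union",
    "all_pair_count",
    "clustered_pair_count",
]

#: |W| above which the pipeline switches from exhaustive to ACO search.
DEFAULT_SWITCH_CUTOFF = 2000


@dataclass
class CandidateSet:
    """Candidate two-locus combinations W retained by the screen.

    ``pairs`` rows are (i, j) with i < j; ``cmi`` the screening score of
    each pair, ``chi2_p`` the pairwise chi-square p-value when the
    co-filter was enabled (NaN otherwise) and ``cluster`` the cluster
    each pair came from.  Rows are sorted by descending cMI.
    """

    pairs: np.ndarray
    cmi: np.ndarray
    cluster: np.ndarray
    chi2_p: np.ndarray
    tau: float
    chi2_p_max: float | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_i": self.pairs[:, 0], "snp_j": self.pairs[:, 1],
            "cluster": self.cluster, "cmi": self.cmi, "chi2_p": self.chi2_p,
        })


def screen_pairs(
    g: GenotypeMatrix,
    clusters: ClusterState,
    tau: float = 0.02,
    chi2_p_max: float | None = None,
    pairwise_df: int = 8,
) -> CandidateSet:
    """Retain within-cluster pairs with cMI > tau (and, optionally, a
    pairwise chi-square p-value below ``chi2_p_max``)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    pairs, scores, labels = [], [], []
    for m in range(clusters.k):
        members = clusters.members(m)
        if members.size < 2:
            continue
        cmi = mi_matrix(g, members, cases_only=True)
        iu, ju = np.triu_indices(members.size, k=1)
        keep = cmi[iu, ju] > tau
        pairs.append(np.column_stack([members[iu[keep]], members[ju[keep]]]))
        scores.append(cmi[iu[keep], ju[keep]])
        labels.append(np.full(int(keep.sum()), m, dtype=np.int64))
    if pairs:
        pairs = np.concatenate(pairs)
        scores = np.concatenate(scores)
        labels = np.concatenate(labels)
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
        scores = np.empty(0)
        labels = np.empty(0, dtype=np.int64)

    chi2_p = np.full(len(pairs), np.nan)
    if chi2_p_max is not None and len(pairs):
        _, chi2_p = batch_chi2(g, pairs, df=pairwise_df)
        keep = chi2_p < chi2_p_max
        pairs, scores, labels, chi2_p = pairs[keep], scores[keep], labels[keep], chi2_p[keep]

    order = np.lexsort((pairs[:, 1], pairs[:, 0], -scores))
    return CandidateSet(
        pairs=pairs[order], cmi=scores[order], cluster=labels[order],
        chi2_p=chi2_p[order], tau=tau, chi2_p_max=chi2_p_max,
    )


def candidate_snp_union(w: CandidateSet) -> np.ndarray:
    """Sorted unique SNP indices appearing in any retained pair."""
    return np.unique(w.pairs)


def all_pair_count(m: int) -> int:
    """Number of two-locus combinations among m SNPs, C(m, 2)."""
    return comb(m, 2)


def clustered_pair_count(m: int, k: int) -> int:
    """Pairs left to examine after splitting m SNPs into k equal groups:
    k * C(m/k, 2) — the screening-stage search-space reduction."""
    if m % k:
        sizes = [m // k + (1 if i < m % k else 0) for i in range(k)]
        return sum(comb(s, 2) for s in sizes)
    return k * comb(m // k, 2)
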