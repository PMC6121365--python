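"""Stage 2, small candidate sets: exhaustive K-locus search.

All K-subsets of the candidate SNP union are scored with the K-locus
chi-square statistic; combinations whose p-value beats the Bonferroni-
corrected level alpha0 / C(M, K) are flagged significant.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .infotheory import batch_chi2, bonferroni_threshold
from .screening import CandidateSet, candidate_snp_union

__all__ = ["InteractionResult", "exhaustive_k_search", "results_frame"]


@dataclass(frozen=True)
class InteractionResult:
    """A scored K-SNP combination."""

    loci: tuple[int, ...]
    statistic: float
    df: int
    p_value: float
    alpha_corrected: float
    significant: bool


def _make_results(
    combos: np.ndarray, stats: np.ndarray, pvals: np.ndarray, df: int, alpha: float
) -> list[InteractionResult]:
    order = np.lexsort(tuple(combos[:, c] for c in reversed(range(combos.shape[1]))) + (pvals,))
    return [
        InteractionResult(
            loci=tuple(int(x) for x in combos[i]),
            statistic=float(stats[i]),
            df=df,
            p_value=float(pvals[i]),
            alpha_corrected=alpha,
            significant=bool(pvals[i] < alpha),
        )
        for i in order
    ]


def exhaustive_k_search(
    g: GenotypeMatrix,
    w: CandidateSet,
    K: int = 3,
    alpha0: float = 0.05,
    correction_M: str = "total_snps",
    combination_warn: int = 10_000_000,
) -> list[InteractionResult]:
    """Score every K-subset of the candidate SNP union.

    ``correction_M`` picks the SNP count entering the Bonferroni
    correction: ``"total_snps"`` (conservative default: all M SNPs of the
    dataset) or ``"candidate_snps"`` (the screened union only).
    """
    union = candidate_snp_union(w)
    if union.size < K:
        raise ValueError(
            f"candidate union holds {union.size} SNPs; cannot form {K}-subsets"
        )
    n_combos = comb(union.size, K)
    if n_combos > combination_warn:
        import warnings

        warnings.warn(
            f"exhaustive search over {n_combos} {K}-subsets; consider the ACO search",
            stacklevel=2,
        )
    m_star = g.n_snps if correction_M == "total_snps" else union.size
    alpha = bonferroni_threshold(alpha0, m_star, K)
    combos = np.fromiter(
        (x for c in combinations(union.tolist(), K) for x in c), dtype=np.intp
    ).reshape(-1, K)
    stats, pvals = batch_chi2(g, combos)
    return _make_results(combos, stats, pvals, 3**K - 1, alpha)


def results_frame(results: list[InteractionResult], snp_ids=None) -> pd.DataFrame:
    """Tabulate interaction results (optionally mapping indices to IDs)."""
    rows = []
    for r in results:
        ids = ",".join(snp_ids[i] for i in r.loci) if snp_ids else ",".join(map(str, r.loci))
        rows.append((ids, r.statistic, r.df, r.p_value, r.alpha_corrected, r.significant))
    return pd.DataFrame(
        rows, columns=["snp_ids", "chi2", "df", "p", "alpha_corrected", "significant"]
    )
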