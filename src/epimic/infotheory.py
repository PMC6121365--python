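"""Information-theoretic and chi-square statistics on genotype data.

All scores are plug-in (maximum-likelihood) estimates over 3x3 (pairwise)
or 3**K x 2 (K-locus, phenotype-stratified) contingency tables.
Logarithms are natural, so mutual-information values are in nats; the
screening threshold tau used elsewhere in the package is on the same
scale.  Samples with a missing call at any queried locus are excluded
from that query.

Besides the single-pair operations, this module provides batched kernels:
``mi_matrix`` computes all pairwise MI values among a set of SNPs through
one one-hot matrix product (exact integer counts in float32), and
``batch_chi2`` scores many K-locus combinations at once through the
bit-set index.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from ._bitops import popcount
from .genotype import GenotypeMatrix, joint_counts

__all__ = [
    "MIScore",
    "ChiSquareResult",
    "mutual_information",
    "conditional_mutual_information",
    "chi_square_test",
    "bonferroni_threshold",
    "mi_matrix",
    "mi_against",
    "batch_chi2",
    "entropy",
]


@dataclass(frozen=True)
class MIScore:
    """Mutual information in nats together with the sample count used."""

    value: float
    n_effective: int


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    loci: tuple[int, ...]


class UndefinedScoreError(ValueError):
    """Raised when a score has no usable samples."""


def _mi_from_table(table: np.ndarray) -> MIScore:
    n = table.sum()
    if n == 0:
        raise UndefinedScoreError("no jointly non-missing samples")
    p = table / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * pj))
    return MIScore(float(np.nansum(terms)), int(n))


def mutual_information(g: GenotypeMatrix, i: int, j: int) -> MIScore:
    """Plug-in mutual information between SNPs ``i`` and ``j`` over all
    jointly called samples.  ``i == j`` yields the genotype entropy."""
    if i == j:
        counts = joint_counts(g, [i])
        return _mi_from_table(np.diag(counts))
    # canonical order makes the score exactly symmetric in (i, j)
    return _mi_from_table(joint_counts(g, sorted((i, j))).astype(float))


def conditional_mutual_information(g: GenotypeMatrix, i: int, j: int) -> MIScore:
    """Mutual information between SNPs ``i`` and ``j`` restricted to case
    samples (phenotype 1) — the screening score of stage 1."""
    if i == j:
        table = np.diag(joint_counts(g, [i], stratify_by_phenotype=True)[..., 1])
    else:
        table = joint_counts(g, sorted((i, j)), stratify_by_phenotype=True)[..., 1]
    if table.sum() == 0:
        raise UndefinedScoreError("no jointly called case samples")
    return _mi_from_table(table.astype(float))


def entropy(g: GenotypeMatrix, i: int) -> float:
    """Genotype entropy of SNP ``i`` in nats (equals its self-MI)."""
    return mutual_information(g, i, i).value


def _chi2_from_table(table: np.ndarray, df: int) -> tuple[float, float]:
    """Pearson statistic on a (rows x 2) table; zero-marginal rows are
    skipped and contribute nothing."""
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / n
    keep = expected > 0
    stat = float(((table[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    return stat, float(_chi2_dist.sf(stat, df=df))


def chi_square_test(
    g: GenotypeMatrix, loci, df_override: int | None = None
) -> ChiSquareResult:
    """K-locus chi-square association test on the 3**K x 2 genotype-by-
    phenotype table.  The default degrees of freedom are 3**K - 1."""
    loci = tuple(sorted(loci))
    table = joint_counts(g, loci, stratify_by_phenotype=True).reshape(-1, 2)
    if (table.sum(axis=0) == 0).any():
        raise ValueError("both phenotype classes must be present among called samples")
    df = df_override if df_override is not None else 3 ** len(loci) - 1
    stat, p = _chi2_from_table(table.astype(float), df)
    return ChiSquareResult(stat, df, p, loci)


def bonferroni_threshold(alpha0: float, M: int, K: int) -> float:
    """Bonferroni-corrected level alpha0 / C(M, K), with the binomial
    coefficient computed in exact integer arithmetic."""
    if not 0 < alpha0 <= 1:
        raise ValueError("alpha0 must be in (0, 1]")
    if not 1 <= K <= M:
        raise ValueError(f"need 1 <= K <= M, got K={K}, M={M}")
    return alpha0 / comb(M, K)


# ---------------------------------------------------------------------------
# Batched kernels
# ---------------------------------------------------------------------------

def _onehot_f32(genotypes: np.ndarray) -> np.ndarray:
    """(n, 3m) float32 one-hot of a (n, m) coded genotype block.  Missing
    calls produce an all-zero row for that SNP, which excludes the sample
    from every count involving it."""
    n, m = genotypes.shape
    out = np.zeros((n, 3 * m), dtype=np.float32)
    for u in range(3):
        out[:, u * m:(u + 1) * m] = genotypes == u + 1
    return out


def mi_matrix(
    g: GenotypeMatrix, indices, cases_only: bool = False
) -> np.ndarray:
    """All pairwise plug-in MI values among ``indices``.

    The 9 joint-count tables of every pair are obtained from a single
    one-hot Gram matrix (exact: counts are small integers in float32).
    The diagonal holds each SNP's entropy.  With ``cases_only`` the
    computation is restricted to the case stratum, turning the result
    into the conditional-MI screening matrix.
    """
    indices = np.asarray(indices, dtype=np.intp)
    return mi_cross(g, indices, indices, cases_only=cases_only)


def _mi_from_cell_counts(c: np.ndarray) -> np.ndarray:
    """MI over trailing (3, 3) joint-count axes of an array."""
    n = c.sum(axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = c / n[..., None, None]
        pi = p.sum(axis=-1, keepdims=True)
        pj = p.sum(axis=-2, keepdims=True)
        terms = p * np.log(p / (pi * pj))
    return np.nansum(terms, axis=(-2, -1))


def mi_cross(
    g: GenotypeMatrix, rows, cols, cases_only: bool = False
) -> np.ndarray:
    """Pairwise MI between two index sets, shape (len(rows), len(cols)).
    Same counting backend as :func:`mi_matrix`."""
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    geno = g.genotypes
    if cases_only:
        geno = geno[g.phenotype == 1]
    xr = _onehot_f32(geno[:, rows])
    xc = _onehot_f32(geno[:, cols])
    counts = (xr.T @ xc).astype(np.float64)
    c = counts.reshape(3, len(rows), 3, len(cols)).transpose(1, 3, 0, 2)
    return _mi_from_cell_counts(c)


def mi_against(
    g: GenotypeMatrix, targets, cases_only: bool = False
) -> np.ndarray:
    """MI of every SNP against each SNP in ``targets``; returns an array
    of shape (M, len(targets)).  Used to assign SNPs to centroids; counts
    come from the packed bit-set index."""
    targets = np.asarray(targets, dtype=np.intp)
    bits = g.geno_bits
    out = np.empty((g.n_snps, len(targets)), dtype=np.float64)
    stratum = g.pheno_bits[1] if cases_only else None
    for t_pos, t in enumerate(targets):
        c = np.empty((g.n_snps, 3, 3), dtype=np.float64)
        for u in range(3):
            for v in range(3):
                mask = bits[:, u] & bits[t, v]
                if stratum is not None:
                    mask = mask & stratum
                c[:, u, v] = popcount(mask)
        out[:, t_pos] = _mi_from_cell_counts(c)
    return out


def batch_chi2(
    g: GenotypeMatrix,
    combos: np.ndarray,
    df: int | None = None,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square statistics and p-values for many K-locus combinations.

    ``combos`` is an (n_combos, K) integer array.  Counting walks the
    3**K joint genotypes once per chunk through the packed bit-sets.
    """
    combos = np.asarray(combos, dtype=np.intp)
    if combos.ndim != 2:
        raise ValueError("combos must be 2-D (n_combos, K)")
    n_combos, k = combos.shape
    if df is None:
        df = 3**k - 1
    bits = g.geno_bits
    case_bits = g.pheno_bits[1]
    n_cells = 3**k
    stats = np.empty(n_combos, dtype=np.float64)
    cell_codes = np.array(
        np.meshgrid(*([range(3)] * k), indexing="ij")
    ).reshape(k, -1).T  # (3**K, K)
    for start in range(0, n_combos, chunk):
        sl = combos[start:start + chunk]
        b = sl.shape[0]
        table = np.empty((b, n_cells, 2), dtype=np.float64)
        for idx, codes in enumerate(cell_codes):
            mask = bits[sl[:, 0], codes[0]]
            for col in range(1, k):
                mask = mask & bits[sl[:, col], codes[col]]
            total = popcount(mask)
            case = popcount(mask & case_bits)
            table[:, idx, 0] = total - case
            table[:, idx, 1] = case
        n = table.sum(axis=(1, 2))
        row = table.sum(axis=2)
        col = table.sum(axis=1)
        expected = row[..., None] * col[:, None, :] / n[:, None, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (table - expected) ** 2 / expected
        stats[start:start + chunk] = np.nansum(contrib, axis=(1, 2))
    return stats, _chi2_dist.sf(stats, df=df)
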