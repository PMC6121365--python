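"""Case-control simulator with three planted interacting disease loci.

Datasets mirror the standard benchmark protocol for epistasis detectors:
three disease loci with equal minor-allele frequency follow a chosen
three-locus penetrance model whose single free effect parameter theta is
calibrated so the marginal effect size

    lambda = [p_Aa / (1 - p_Aa)] / [p_AA / (1 - p_AA)] - 1

(the heterozygote-versus-wildtype marginal penetrance odds ratio minus
one) hits a requested target.  Background SNPs are independent draws
under Hardy-Weinberg equilibrium.  Optionally the disease loci are left
ungenotyped and replaced by linkage-disequilibrium proxy markers at a
target r-squared.

Disease models
--------------
1. multiplicative: f = p0 * (1 + theta) ** (a1 + a2 + a3), with a_i the
   minor-allele count at locus i;
2. threshold: f = p0 * (1 + theta) iff every locus carries at least one
   minor allele;
3. additive: f = min(1, p0 * (1 + theta * (a1 + a2 + a3)));
4. special threshold: f = p0 * (1 + theta) iff at least two loci carry a
   minor allele;
5. three-locus pattern interaction: f = p0 * (1 + theta) ** e(g), a
   benchmark-style penetrance pattern over joint-genotype classes
   written as sorted minor-allele-count triples: e = 1 on the
   single-carrier class {0,0,1}, e = 2 on the mixed classes {0,1,2},
   {1,1,2} and {1,2,2}, e = 0 elsewhere.  Unlike a multiplicative
   form, this pattern does not factorise across loci among cases, so
   the planted loci carry strong joint dependence both in the case
   stratum (feeding the pair screen) and in the pooled case-control
   sample.

Custom penetrance forms can be supplied as a callable mapping the
(a1, a2, a3) minor-allele counts and theta to a penetrance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import brentq

from .genotype import GenotypeMatrix

__all__ = [
    "DiseaseModelSpec",
    "PenetranceTable",
    "SimulatedDataset",
    "hwe_genotype_freqs",
    "build_penetrance",
    "sample_ld_marker",
    "simulate_dataset",
    "estimate_lambda",
]


def hwe_genotype_freqs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2) for
    minor-allele frequency p."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    return ((1 - maf) ** 2, 2 * maf * (1 - maf), maf**2)


#: joint-genotype classes (sorted minor-allele-count triples) -> exponent
_MODEL5_PATTERN = {
    (0, 0, 0): 0, (0, 0, 1): 1, (0, 0, 2): 0, (0, 1, 1): 0, (0, 1, 2): 2,
    (0, 2, 2): 0, (1, 1, 1): 0, (1, 1, 2): 2, (1, 2, 2): 2, (2, 2, 2): 0,
}


def _model5_exponent(a: tuple[int, int, int]) -> int:
    return _MODEL5_PATTERN[tuple(sorted(a))]


_MODEL_FORMS = {
    1: lambda a, th, p0: p0 * (1 + th) ** sum(a),
    2: lambda a, th, p0: p0 * (1 + th) if min(a) >= 1 else p0,
    3: lambda a, th, p0: min(1.0, p0 * (1 + th * sum(a))),
    4: lambda a, th, p0: p0 * (1 + th) if sum(x >= 1 for x in a) >= 2 else p0,
    5: lambda a, th, p0: p0 * (1 + th) ** _model5_exponent(a),
}

#: conventional marginal effect sizes of the benchmark protocol
DEFAULT_LAMBDA = {1: 0.2, 2: 0.3, 3: 0.3, 4: 0.3, 5: 0.3}


@dataclass(frozen=True)
class DiseaseModelSpec:
    """Configuration of the planted three-locus disease model."""

    model_id: int = 5
    lambda_target: float = 0.3
    maf: float = 0.4
    prevalence_p0: float = 0.01
    r2: float = 1.0
    form: object = None  # optional callable (a, theta, p0) -> penetrance

    def __post_init__(self):
        if self.lambda_target < 0:
            raise ValueError("lambda_target must be >= 0")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0 < self.prevalence_p0 < 1:
            raise ValueError("prevalence_p0 must be in (0, 1)")
        if not 0 < self.r2 <= 1:
            raise ValueError("r2 must be in (0, 1]")
        if self.form is None and self.model_id not in _MODEL_FORMS:
            raise ValueError(f"unknown model_id {self.model_id}")

    @property
    def penetrance_form(self):
        return self.form if self.form is not None else _MODEL_FORMS[self.model_id]


@dataclass
class PenetranceTable:
    """Penetrance f(g1, g2, g3) over the 27 joint genotypes (axes indexed
    by minor-allele count 0/1/2), with the calibrated effect parameter."""

    values: np.ndarray
    theta: float
    lambda_achieved: float

    def marginal_penetrance(self, maf: float) -> tuple[float, float]:
        """(p_AA, p_Aa) of locus 1 averaging over loci 2 and 3 under HWE
        (the table is symmetric, so the locus choice is immaterial)."""
        w = np.array(hwe_genotype_freqs(maf))
        marg = np.einsum("ijk,j,k->i", self.values, w, w)
        return float(marg[0]), float(marg[1])


def _lambda_of(table: np.ndarray, maf: float) -> float:
    w = np.array(hwe_genotype_freqs(maf))
    marg = np.einsum("ijk,j,k->i", table, w, w)
    p_aa, p_het = marg[0], marg[1]
    return (p_het / (1 - p_het)) / (p_aa / (1 - p_aa)) - 1


def _table_for(form, theta: float, p0: float) -> np.ndarray:
    t = np.empty((3, 3, 3))
    for a in product(range(3), repeat=3):
        t[a] = form(a, theta, p0)
    return t


def build_penetrance(spec: DiseaseModelSpec, tol: float = 1e-10) -> PenetranceTable:
    """Calibrate theta by bracketed root finding so the marginal effect
    size matches ``spec.lambda_target``.

    Raises a calibration error when the target cannot be reached with
    every penetrance <= 1.
    """
    form, p0, maf = spec.penetrance_form, spec.prevalence_p0, spec.maf
    target = spec.lambda_target

    def objective(theta: float) -> float:
        return _lambda_of(_table_for(form, theta, p0), maf) - target

    if target == 0:
        table = _table_for(form, 0.0, p0)
        return PenetranceTable(table, 0.0, _lambda_of(table, maf))

    def valid(theta: float) -> bool:
        table = _table_for(form, theta, p0)
        return bool(table.max() <= 1 and np.isfinite(table).all())

    # expand the upper bracket while the table stays a valid penetrance
    hi, hi_valid = 1e-9, 0.0
    while hi < 1e9:
        if not valid(hi):
            # lambda can rise steeply towards the validity boundary:
            # bisect up to it before giving up on the target
            lo = hi_valid
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if valid(mid):
                    lo = mid
                else:
                    hi = mid
            hi_valid = lo
            break
        hi_valid = hi
        if _lambda_of(_table_for(form, hi, p0), maf) >= target:
            break
        hi *= 1.25
    max_lam = _lambda_of(_table_for(form, hi_valid, p0), maf)
    if max_lam < target:
        raise ValueError(
            f"lambda={target} unattainable for model {spec.model_id} at "
            f"maf={maf}, p0={p0}: max feasible lambda ~ {max_lam:.4g} "
            "(penetrance would exceed 1)"
        )
    theta = brentq(objective, 0.0, hi_valid, xtol=tol)
    table = _table_for(form, theta, p0)
    return PenetranceTable(table, float(theta), float(_lambda_of(table, maf)))


# ---------------------------------------------------------------------------
# LD proxy markers
# ---------------------------------------------------------------------------

def sample_ld_marker(
    disease_haplotypes: np.ndarray, r2: float, maf_marker: float, rng
) -> np.ndarray:
    """Marker genotypes in LD with a disease locus.

    ``disease_haplotypes`` is an (n, 2) 0/1 array of minor-allele
    indicators per chromosome.  The marker allele is drawn per haplotype
    from the two-locus haplotype distribution with positive coupling
    D = sqrt(r2 * pD (1 - pD) pM (1 - pM)); with equal frequencies and
    r2 = 1 the marker reproduces the disease locus exactly.
    """
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    hap = np.asarray(disease_haplotypes)
    p = maf_marker
    # equal-frequency convention: disease MAF equals marker MAF, so the
    # Frechet bound on D is p(1-p) and sqrt(r2)*p*(1-p) never exceeds it
    d_coef = np.sqrt(r2) * p * (1 - p)
    if d_coef > p * (1 - p) + 1e-12:
        raise ValueError("requested LD exceeds the attainable bound")
    p_m_given_d = np.clip((p * p + d_coef) / p, 0, 1)
    p_m_given_nd = np.clip((p * (1 - p) - d_coef) / (1 - p), 0, 1)
    probs = np.where(hap == 1, p_m_given_d, p_m_given_nd)
    marker_alleles = rng.random(hap.shape) < probs
    return marker_alleles.sum(axis=1).astype(np.uint8) + 1  # codes 1/2/3


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A simulated matrix plus ground truth: the indices of the three
    genotyped disease (or proxy) markers."""

    matrix: GenotypeMatrix
    truth: tuple[int, int, int]
    spec: DiseaseModelSpec
    seed: object = None
    penetrance: PenetranceTable = field(default=None)  # type: ignore[assignment]


def _draw_disease_block(
    spec: DiseaseModelSpec, table: np.ndarray, n_cases: int, n_controls: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample genotypes at the three genotyped disease/proxy
    markers until both phenotype pools are full.  Returns (genotypes
    coded 1..3 of shape (N, 3), phenotype) with cases last."""
    need = {0: n_controls, 1: n_cases}
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    use_ld = spec.r2 < 1

    def short(v: int) -> int:
        return need[v] - sum(arr.shape[0] for arr in got[v])

    batch = max(4 * (n_cases + n_controls), 10_000)
    while short(0) > 0 or short(1) > 0:
        hap = (rng.random((batch, 3, 2)) < spec.maf).astype(np.int8)
        disease_geno = hap.sum(axis=2)  # minor-allele counts 0..2
        f = table[disease_geno[:, 0], disease_geno[:, 1], disease_geno[:, 2]]
        is_case = rng.random(batch) < f
        if use_ld:
            marker = np.empty((batch, 3), dtype=np.uint8)
            for j in range(3):
                marker[:, j] = sample_ld_marker(hap[:, j, :], spec.r2, spec.maf, rng)
        else:
            marker = (disease_geno + 1).astype(np.uint8)
        for v, mask in ((1, is_case), (0, ~is_case)):
            deficit = short(v)
            if deficit > 0:
                got[v].append(marker[mask][:deficit])
    controls = np.concatenate(got[0])[:n_controls]
    cases = np.concatenate(got[1])[:n_cases]
    geno = np.concatenate([controls, cases])
    pheno = np.concatenate([
        np.zeros(n_controls, dtype=np.uint8), np.ones(n_cases, dtype=np.uint8)
    ])
    return geno, pheno


def simulate_dataset(
    spec: DiseaseModelSpec,
    n_cases: int,
    n_controls: int,
    m_snps: int,
    seed,
    background_maf_range: tuple[float, float] = (0.05, 0.5),
) -> SimulatedDataset:
    """Simulate a case-control dataset of ``m_snps`` SNPs with three
    planted disease markers at seeded random positions.

    Background SNPs are independent HWE draws with per-SNP MAF uniform
    over ``background_maf_range``; the disease block is rejection-
    sampled from the calibrated penetrance model (controls are strictly
    unaffected individuals).  Deterministic given ``seed``.
    """
    if m_snps < 3:
        raise ValueError("need at least 3 SNPs")
    rng = np.random.default_rng(seed)
    table = build_penetrance(spec)
    disease_geno, pheno = _draw_disease_block(
        spec, table.values, n_cases, n_controls, rng
    )
    n = n_cases + n_controls

    geno = np.empty((n, m_snps), dtype=np.uint8)
    truth = np.sort(rng.choice(m_snps, size=3, replace=False))
    background_cols = np.setdiff1d(np.arange(m_snps), truth)
    mafs = rng.uniform(*background_maf_range, size=background_cols.size)
    freqs = np.stack([hwe_genotype_freqs(p) for p in mafs])  # (B, 3)
    cum = np.cumsum(freqs, axis=1)
    u = rng.random((n, background_cols.size))
    geno[:, background_cols] = 1 + (u[:, :, None] > cum[None, :, :2]).sum(axis=2)
    geno[:, truth] = disease_geno

    # shuffle samples so phenotype blocks are interleaved
    order = rng.permutation(n)
    matrix = GenotypeMatrix(geno[order], pheno[order])
    return SimulatedDataset(
        matrix=matrix, truth=tuple(int(t) for t in truth), spec=spec,
        seed=seed, penetrance=table,
    )


def estimate_lambda(g: GenotypeMatrix, locus: int) -> float:
    """Marginal effect size estimated from the case-control 3x2 table at
    ``locus`` via the odds-ratio form, which is invariant to case-control
    sampling: odds(case | Aa) / odds(case | AA) - 1."""
    col = g.genotypes[:, locus]
    y = g.phenotype
    n_case_aa = int(((col == 1) & (y == 1)).sum())
    n_case_het = int(((col == 2) & (y == 1)).sum())
    n_ctrl_aa = int(((col == 1) & (y == 0)).sum())
    n_ctrl_het = int(((col == 2) & (y == 0)).sum())
    if 0 in (n_case_aa, n_case_het, n_ctrl_aa, n_ctrl_het):
        raise ValueError("zero cell: lambda estimate undefined at this locus")
    return (n_case_het / n_ctrl_het) / (n_case_aa / n_ctrl_aa) - 1
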