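"""Shared fixtures: small deterministic genotype matrices and simulated
datasets, all generated programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from epimic import DiseaseModelSpec, GenotypeMatrix, simulate_dataset


def random_matrix(
    n_samples: int = 60, n_snps: int = 8, seed: int = 0, missing_rate: float = 0.0
) -> GenotypeMatrix:
    """Random genotype matrix with roughly balanced phenotype."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(1, 4, size=(n_samples, n_snps)).astype(np.uint8)
    if missing_rate:
        geno[rng.random(geno.shape) < missing_rate] = 0
    pheno = (np.arange(n_samples) % 2).astype(np.uint8)
    return GenotypeMatrix(geno, rng.permutation(pheno))


@pytest.fixture
def small_random():
    return random_matrix()


@pytest.fixture(scope="session")
def planted_dataset():
    """One simulated headline-style dataset, shared across tests:
    Model 5, lambda 0.3, MAF 0.4, 400/400 samples, 60 SNPs."""
    spec = DiseaseModelSpec(model_id=5, lambda_target=0.3, maf=0.4)
    return simulate_dataset(spec, 400, 400, 60, seed=20240901)


def block_matrix(
    n_samples: int = 300, block_sizes=(15, 15), noise_flip: float = 0.05, seed: int = 1
) -> tuple[GenotypeMatrix, np.ndarray]:
    """SNPs in correlated blocks: each block copies a template SNP with a
    small fraction of genotype flips, so within-block MI >> between-block
    MI.  Returns (matrix, true block label per SNP)."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for b, size in enumerate(block_sizes):
        template = rng.integers(1, 4, size=n_samples)
        for _ in range(size):
            col = template.copy()
            flip = rng.random(n_samples) < noise_flip
            col[flip] = rng.integers(1, 4, size=int(flip.sum()))
            cols.append(col)
            labels.append(b)
    geno = np.column_stack(cols).astype(np.uint8)
    pheno = (np.arange(n_samples) % 2).astype(np.uint8)
    return GenotypeMatrix(geno, pheno), np.array(labels)
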