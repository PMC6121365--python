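"""Genotype/phenotype data model, text I/O and quality control.

The canonical in-memory container is :class:`GenotypeMatrix`: ``N``
samples by ``M`` biallelic SNPs with genotypes coded ``1`` (homozygous
major, AA), ``2`` (heterozygous, Aa), ``3`` (homozygous minor, aa) and
``0`` for a missing call, together with a binary phenotype (0 = control,
1 = case).  Joint-genotype contingency counting is backed by per-genotype
packed bit-sets (:mod:`epimic._bitops`), the workhorse of every statistic
in the package.

Two text formats are supported: a canonical TSV (one row per sample,
first column the phenotype, remaining columns genotype codes) and PLINK
PED/MAP text files, with alleles recoded so the minor allele in the
dataset defines codes 2/3.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from ._bitops import pack_bool, popcount

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "load_genotypes",
    "save_genotypes_tsv",
    "qc_filter",
    "joint_counts",
    "hwe_chi2_pvalue",
]

CODES = (1, 2, 3)
MISSING = 0


class GenotypeParseError(ValueError):
    """Raised for malformed genotype input files."""


@dataclass
class GenotypeMatrix:
    """Case-control genotype matrix with packed bit-set indexes.

    Attributes
    ----------
    genotypes : (N, M) uint8 array with values in {0, 1, 2, 3}.
    phenotype : (N,) uint8 array with values in {0, 1}.
    snp_ids : list of M SNP identifiers.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.uint8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.uint8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (samples x SNPs) array")
        if self.phenotype.shape != (self.genotypes.shape[0],):
            raise ValueError("phenotype length must equal the number of samples")
        if self.genotypes.max(initial=0) > 3:
            raise ValueError("genotype codes must be in {0, 1, 2, 3}")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary (0 = control, 1 = case)")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{i}" for i in range(self.n_snps)]
        if len(self.snp_ids) != self.n_snps:
            raise ValueError("snp_ids length must equal the number of SNPs")
        self._geno_bits: np.ndarray | None = None
        self._pheno_bits: np.ndarray | None = None

    # -- basic dimensions -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    # -- bit-set indexes ---------------------------------------------------
    @property
    def geno_bits(self) -> np.ndarray:
        """(M, 3, n_words) packed membership sets per SNP and genotype."""
        if self._geno_bits is None:
            onehot = np.stack(
                [self.genotypes.T == c for c in CODES], axis=1
            )  # (M, 3, N)
            self._geno_bits = pack_bool(onehot)
        return self._geno_bits

    @property
    def pheno_bits(self) -> np.ndarray:
        """(2, n_words) packed membership sets for controls and cases."""
        if self._pheno_bits is None:
            self._pheno_bits = pack_bool(
                np.stack([self.phenotype == 0, self.phenotype == 1])
            )
        return self._pheno_bits

    def case_onehot(self) -> np.ndarray:
        """(N1, M, 3) boolean one-hot genotypes of the case stratum."""
        g = self.genotypes[self.phenotype == 1]
        return np.stack([g == c for c in CODES], axis=-1)

    # -- convenience -------------------------------------------------------
    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        g, y, ids = self.genotypes, self.phenotype, self.snp_ids
        if samples is not None:
            g, y = g[samples], y[samples]
        if snps is not None:
            g = g[:, snps]
            ids = [ids[i] for i in np.arange(self.n_snps)[snps]]
        return GenotypeMatrix(g, y, list(ids))


def joint_counts(
    g: GenotypeMatrix, loci, stratify_by_phenotype: bool = False
) -> np.ndarray:
    """Contingency counts over the 3**K joint genotypes of ``loci``.

    Samples missing a call at any queried locus are excluded.  With
    ``stratify_by_phenotype`` the returned array has a trailing axis of
    length 2 (controls, cases).  Counts are computed by bit-set
    intersection and population count.
    """
    loci = list(loci)
    if len(set(loci)) != len(loci):
        raise ValueError("duplicate loci in joint_counts query")
    if not loci:
        raise ValueError("at least one locus required")
    for i in loci:
        if not 0 <= i < g.n_snps:
            raise IndexError(f"SNP index {i} out of range")
    bits = g.geno_bits
    k = len(loci)
    shape = (3,) * k + ((2,) if stratify_by_phenotype else ())
    out = np.zeros(shape, dtype=np.int64)
    for combo in product(range(3), repeat=k):
        mask = bits[loci[0], combo[0]]
        for locus, c in zip(loci[1:], combo[1:]):
            mask = mask & bits[locus, c]
        if stratify_by_phenotype:
            for v in (0, 1):
                out[combo + (v,)] = popcount(mask & g.pheno_bits[v])
        else:
            out[combo] = popcount(mask)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    """Write the canonical TSV: header, then one row per sample with the
    phenotype in the first column and genotype codes after it."""
    df = pd.DataFrame(g.genotypes, columns=g.snp_ids)
    df.insert(0, "phenotype", g.phenotype)
    df.to_csv(path, sep="\t", index=False)


def _load_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        first = fh.readline()
    has_header = not first.split("\t")[0].strip().lstrip("-").isdigit()
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: need a phenotype column and >=1 SNP")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.isnan(arr.astype(float)).any():
        bad = int(np.where(df.isna().any(axis=1) | ~df.map(np.isreal))[0][0]) + 1
        raise GenotypeParseError(f"{path}: non-numeric or missing field at data line {bad}")
    y = arr[:, 0]
    if not np.isin(y, (0, 1)).all():
        bad = int(np.where(~np.isin(y, (0, 1)))[0][0]) + 1
        raise GenotypeParseError(f"{path}: phenotype not binary at data line {bad}")
    geno = arr[:, 1:]
    if not np.isin(geno, (0, 1, 2, 3)).all():
        bad = int(np.where(~np.isin(geno, (0, 1, 2, 3)).all(axis=1))[0][0]) + 1
        raise GenotypeParseError(f"{path}: genotype code outside {{0,1,2,3}} at data line {bad}")
    ids = [str(c) for c in df.columns[1:]] if has_header else None
    return GenotypeMatrix(geno.astype(np.uint8), y.astype(np.uint8), ids)


def _load_ped(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    snp_ids = None
    if map_path.exists():
        snp_ids = [ln.split()[1] for ln in map_path.read_text().splitlines() if ln.strip()]
    rows, phenos = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 8 or (len(fields) - 6) % 2:
                raise GenotypeParseError(
                    f"{ped_path}: line {lineno} has a malformed field count ({len(fields)})"
                )
            pheno = fields[5]
            if pheno not in ("1", "2"):
                raise GenotypeParseError(
                    f"{ped_path}: line {lineno} phenotype {pheno!r} is not case/control (1/2)"
                )
            phenos.append(int(pheno) - 1)
            rows.append(fields[6:])
    if not rows:
        raise GenotypeParseError(f"{ped_path}: no samples")
    alleles = np.array(rows, dtype="U8").reshape(len(rows), -1, 2)
    n_snps = alleles.shape[1]
    if snp_ids is not None and len(snp_ids) != n_snps:
        raise GenotypeParseError(
            f"{ped_path}: {n_snps} SNPs in PED but {len(snp_ids)} in {map_path.name}"
        )
    geno = np.zeros((len(rows), n_snps), dtype=np.uint8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise GenotypeParseError(
                f"{ped_path}: SNP column {j + 1} is not biallelic (alleles {list(uniq)})"
            )
        if uniq.size == 0:
            continue  # all missing; stays coded 0
        order = np.argsort(counts)  # minor first on ties by count
        if uniq.size == 1:
            major, minor = uniq[0], None
        else:
            # tie on counts: call the lexicographically later allele minor
            if counts[0] == counts[1]:
                major, minor = sorted(uniq)
            else:
                minor, major = uniq[order[0]], uniq[order[1]]
        missing = (col == "0").any(axis=1)
        n_minor = (col == minor).sum(axis=1) if minor is not None else np.zeros(len(rows), int)
        geno[:, j] = np.where(missing, 0, 1 + n_minor)
    return GenotypeMatrix(geno, np.array(phenos), snp_ids)


def load_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Load a :class:`GenotypeMatrix` from the canonical TSV or a PLINK
    PED/MAP pair.  ``format`` is ``"tsv"`` or ``"plink-ped"``; by default
    it is inferred from the file extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "plink-ped" if path.suffix.lower() == ".ped" else "tsv"
    if format == "tsv":
        return _load_tsv(path)
    if format == "plink-ped":
        return _load_ped(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Record of removals made by :func:`qc_filter`, one row per removed
    SNP or sample with the offending value and the threshold applied."""

    removed_snps: list[tuple[str, str, float, float]] = field(default_factory=list)
    removed_samples: list[tuple[int, str, float, float]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", i, r, v, t) for i, r, v, t in self.removed_snps]
        rows += [("sample", i, r, v, t) for i, r, v, t in self.removed_samples]
        return pd.DataFrame(rows, columns=["kind", "id", "reason", "value", "threshold"])


def hwe_chi2_pvalue(counts) -> float:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg genotype
    proportions, from (n_AA, n_Aa, n_aa) counts."""
    n_aa_major, n_het, n_aa_minor = (float(c) for c in counts)
    n = n_aa_major + n_het + n_aa_minor
    if n == 0:
        return 1.0
    p = (2 * n_aa_minor + n_het) / (2 * n)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    observed = np.array([n_aa_major, n_het, n_aa_minor])
    keep = expected > 0
    stat = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    return float(_chi2_dist.sf(stat, df=1))


def minor_allele_frequency(geno_col: np.ndarray) -> float:
    """MAF of one SNP column (codes {0,1,2,3}); missing calls excluded."""
    called = geno_col[geno_col != MISSING]
    if called.size == 0:
        return 0.0
    return float((called - 1).sum() / (2 * called.size))


def qc_filter(
    g: GenotypeMatrix,
    snp_call_rate: float = 0.95,
    sample_call_rate: float = 0.98,
    hwe_p: float = 1e-4,
    maf_min: float = 0.1,
) -> tuple[GenotypeMatrix, QcReport]:
    """Standard GWAS quality control, applied in a fixed order: SNP call
    rate, sample call rate, Hardy-Weinberg equilibrium in controls, then
    minor-allele frequency."""
    if g.n_cases == 0 or g.n_controls == 0:
        raise ValueError("qc_filter needs at least one case and one control")
    report = QcReport(thresholds=dict(
        snp_call_rate=snp_call_rate, sample_call_rate=sample_call_rate,
        hwe_p=hwe_p, maf_min=maf_min,
    ))

    # 1. SNP call rate
    call = (g.genotypes != MISSING).mean(axis=0)
    keep = call >= snp_call_rate
    for j in np.where(~keep)[0]:
        report.removed_snps.append((g.snp_ids[j], "call_rate", float(call[j]), snp_call_rate))
    g = g.subset(snps=keep)

    # 2. sample call rate
    if g.n_snps:
        scall = (g.genotypes != MISSING).mean(axis=1)
        skeep = scall >= sample_call_rate
        for i in np.where(~skeep)[0]:
            report.removed_samples.append((int(i), "call_rate", float(scall[i]), sample_call_rate))
        g = g.subset(samples=skeep)

    # 3. HWE in controls
    controls = g.genotypes[g.phenotype == 0]
    keep = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        col = controls[:, j]
        p = hwe_chi2_pvalue([(col == c).sum() for c in CODES])
        if p < hwe_p:
            keep[j] = False
            report.removed_snps.append((g.snp_ids[j], "hwe", p, hwe_p))
    g = g.subset(snps=keep)

    # 4. MAF
    keep = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        maf = minor_allele_frequency(g.genotypes[:, j])
        if maf < maf_min:
            keep[j] = False
            report.removed_snps.append((g.snp_ids[j], "maf", maf, maf_min))
    g = g.subset(snps=keep)

    if g.n_snps == 0:
        raise ValueError("empty after QC: every SNP was removed")
    return g, report
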