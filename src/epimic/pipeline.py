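"""End-to-end detection pipeline and the power-evaluation harness.

``detect`` chains the two stages — MI clustering, conditional-MI pair
screening, then either the exhaustive or the ant-colony K-locus search
depending on the candidate-set size.  ``power_experiment`` measures
detection power: the fraction of simulated datasets in which the
reported significant interactions include exactly the planted marker
set (power = DT / D).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import cluster
from .genotype import GenotypeMatrix
from .screening import DEFAULT_SWITCH_CUTOFF, screen_pairs
from .search_aco import AcoConfig, run_aco
from .search_exhaustive import InteractionResult, exhaustive_k_search
from .simulate import DiseaseModelSpec, simulate_dataset

__all__ = ["DetectReport", "PowerResult", "detect", "power_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class DetectReport:
    """Interaction results plus per-stage diagnostics of one run."""

    results: list[InteractionResult]
    cluster_sizes: list[int]
    n_candidates: int
    search_used: str
    k: int
    tau: float


@dataclass
class PowerResult:
    """Detection power over D datasets of one experiment grid point."""

    n_datasets: int
    n_detected: int
    flags: list[bool]
    config: dict = field(default_factory=dict)

    @property
    def power(self) -> float:
        return self.n_detected / self.n_datasets


def detect(
    g: GenotypeMatrix,
    k: int = 3,
    tau: float = 0.02,
    K: int = 3,
    alpha0: float = 0.05,
    search: str = "auto",
    switch_cutoff: int = DEFAULT_SWITCH_CUTOFF,
    seed=None,
    aco_cfg: AcoConfig | None = None,
    chi2_p_max: float | None = None,
    max_reps: int = 50,
    correction_M: str = "total_snps",
) -> DetectReport:
    """Run the full two-stage detection on a genotype matrix.

    ``search="auto"`` follows the size rule: exhaustive for
    |W| <= switch_cutoff, ant-colony beyond.  All randomness (centroid
    init, ACO) flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    state = cluster(g, k=k, seed=rng, max_reps=max_reps)
    sizes = np.bincount(state.assignment, minlength=k).tolist()
    w = screen_pairs(g, state, tau=tau, chi2_p_max=chi2_p_max)
    logger.info("stage 1: cluster sizes %s, |W|=%d", sizes, len(w))

    if len(w) == 0:
        logger.warning("candidate set is empty; no interactions to report")
        return DetectReport([], sizes, 0, "none", k, tau)

    if search == "auto":
        search = "exhaustive" if len(w) <= switch_cutoff else "aco"
    if search == "exhaustive":
        union = np.unique(w.pairs)
        if union.size < K:
            logger.warning(
                "candidate union has %d SNPs (< K=%d); no interactions", union.size, K
            )
            return DetectReport([], sizes, len(w), "exhaustive", k, tau)
        results = exhaustive_k_search(g, w, K=K, alpha0=alpha0, correction_M=correction_M)
    elif search == "aco":
        cfg = aco_cfg or AcoConfig()
        if cfg.seed is None:
            cfg = AcoConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31))})
        results = run_aco(g, w, K=K, cfg=cfg, alpha0=alpha0, correction_M=correction_M)
    else:
        raise ValueError(f"unknown search mode {search!r}")
    logger.info("stage 2 (%s): %d results, %d significant",
                search, len(results), sum(r.significant for r in results))
    return DetectReport(results, sizes, len(w), search, k, tau)


def _detected(report: DetectReport, truth) -> bool:
    """Exact K-set match between a reported significant interaction and
    the planted (genotyped) marker set."""
    truth = tuple(sorted(truth))
    return any(r.loci == truth for r in report.results if r.significant)


def power_experiment(
    spec: DiseaseModelSpec,
    n_cases: int,
    n_controls: int,
    m_snps: int,
    n_datasets: int,
    seed,
    detector=None,
    **detect_kwargs,
) -> PowerResult:
    """Simulate ``n_datasets`` datasets and measure detection power.

    Each dataset gets an independent child seed from ``seed``, so any
    grid point is reproducible in isolation.  ``detector`` may override
    the pipeline (for harness testing); it receives the simulated
    dataset and must return a :class:`DetectReport`.
    """
    master = np.random.SeedSequence(seed)
    flags: list[bool] = []
    for child in master.spawn(n_datasets):
        sim_seed, det_seed = child.spawn(2)
        data = simulate_dataset(spec, n_cases, n_controls, m_snps, seed=sim_seed)
        if detector is None:
            report = detect(data.matrix, seed=det_seed, **detect_kwargs)
        else:
            report = detector(data)
        flags.append(_detected(report, data.truth))
    return PowerResult(
        n_datasets=n_datasets,
        n_detected=sum(flags),
        flags=flags,
        config=dict(
            model=spec.model_id, lam=spec.lambda_target, maf=spec.maf, r2=spec.r2,
            n_cases=n_cases, n_controls=n_controls, m_snps=m_snps, seed=seed,
            **detect_kwargs,
        ),
    )
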