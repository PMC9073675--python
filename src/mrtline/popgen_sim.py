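"""Stochastic simulators for the population-genetic assumptions of the analysis.

Two assumptions underpin the rate and selection inference:

1. A new neutral mutation arising heterozygous in a single-descent MA line
   is ultimately lost with probability 1/2.  Under selfing with one
   surviving offspring per generation, the offspring of a heterozygote is
   homozygous mutant with probability 1/4, heterozygous with probability
   1/2 and homozygous wild type with probability 1/4 — a lazy symmetric
   random walk absorbed at fixation or loss, each with probability 1/2.
   This factor of 1/2 cancels the diploidy factor of 2 in the arisal rate,
   which is why ``U = k/(n*t)`` is the haploid-rate estimate.

2. In a large selfing population, irreversible mutation to a deleterious
   phenotype at genomic rate ``U`` balanced by selection ``s`` holds the
   phenotype near frequency ``U/s``.  :func:`wf_selfing` is a finite-N
   Wright–Fisher version of the deterministic recursion in
   :mod:`mrtline.msb_inference`: N selfing lineages, binomial resampling
   weighted by fitness 1 vs 1-s, irreversible mutation wild-type→Mrt.

:func:`recover_U` closes the inference loop end-to-end: simulate MA
experiments, classify the assay tables, count strong-Mrt lines, estimate
the rate with its exact interval, and report bias and interval coverage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import rate_estimation
from .phenotyping import MrtClass, classify_table
from .synthetic_data import AssayDesign, generate_ma_experiment

__all__ = [
    "TransmissionResult",
    "TransmissionSummary",
    "WrightFisherConfig",
    "RecoveryReport",
    "ma_transmission",
    "ma_transmission_ensemble",
    "wf_selfing",
    "recover_U",
]


@dataclass(frozen=True)
class TransmissionResult:
    """Fate of one new mutation under single-descent selfing propagation."""

    outcome: str  # "fixed" or "lost"
    generations_to_absorption: int


def ma_transmission(
    seed: int | np.random.Generator | None = None,
    start: str = "heterozygous",
) -> TransmissionResult:
    """Track one new mutation through an MA line until fixation or loss.

    Starting from a heterozygote, each generation the single surviving
    selfed offspring is homozygous mutant with probability 1/4 (absorbed:
    fixed), heterozygous with probability 1/2, or homozygous wild type with
    probability 1/4 (absorbed: lost).  A ``start`` of ``"homozygous_mutant"``
    or ``"homozygous_wild_type"`` is already absorbed (0 generations).
    """
    if start == "homozygous_mutant":
        return TransmissionResult("fixed", 0)
    if start == "homozygous_wild_type":
        return TransmissionResult("lost", 0)
    if start != "heterozygous":
        raise ValueError(f"unknown start genotype {start!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gens = 0
    while True:
        gens += 1
        u = rng.random()
        if u < 0.25:
            return TransmissionResult("fixed", gens)
        if u >= 0.75:
            return TransmissionResult("lost", gens)


@dataclass(frozen=True)
class TransmissionSummary:
    """Monte-Carlo summary of many independent transmission walks."""

    n_replicates: int
    n_lost: int
    n_fixed: int
    loss_fraction: float
    mean_generations: float
    max_generations: int
    generations: np.ndarray = field(repr=False)
    outcomes_lost: np.ndarray = field(repr=False)


def ma_transmission_ensemble(
    n_replicates: int, seed: int | None = None
) -> TransmissionSummary:
    """Vectorized ensemble of :func:`ma_transmission` walks from a heterozygote.

    Reports the loss fraction (theoretical value 1/2) and the distribution
    of generations to absorption, so the adequacy of any finite propagation
    horizon can be checked directly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    gens = np.zeros(n_replicates, dtype=np.int64)
    lost = np.zeros(n_replicates, dtype=bool)
    active = np.arange(n_replicates)
    g = 0
    while active.size:
        g += 1
        u = rng.random(active.size)
        absorbed = (u < 0.25) | (u >= 0.75)
        idx = active[absorbed]
        gens[idx] = g
        lost[idx] = u[absorbed] >= 0.75
        active = active[~absorbed]
    return TransmissionSummary(
        n_replicates=n_replicates,
        n_lost=int(lost.sum()),
        n_fixed=int((~lost).sum()),
        loss_fraction=float(lost.mean()),
        mean_generations=float(gens.mean()),
        max_generations=int(gens.max()),
        generations=gens,
        outcomes_lost=lost,
    )


@dataclass(frozen=True)
class WrightFisherConfig:
    """Finite selfing population: N lineages, mutation U, selection s."""

    N: int
    U: float
    s: float
    generations: int
    q0: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 <= self.U <= 1 or not 0 <= self.s <= 1:
            raise ValueError("U and s must be in [0, 1]")
        if not 0 <= self.q0 <= 1:
            raise ValueError("q0 must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def wf_selfing(config: WrightFisherConfig) -> np.ndarray:
    """Wright–Fisher dynamics of the Mrt frequency among N selfing lineages.

    Each generation applies irreversible mutation (each wild-type lineage
    becomes Mrt with probability U) and then multinomial resampling of the
    N lineages with relative fitness 1 vs 1-s — the finite-population
    analogue of the deterministic recursion, matching it as N grows.

    Returns the frequency trajectory of length ``generations + 1``
    (including the initial frequency).
    """
    rng = np.random.default_rng(config.seed)
    N, U, s = config.N, config.U, config.s
    m = int(round(config.q0 * N))
    traj = np.empty(config.generations + 1)
    traj[0] = m / N
    for g in range(1, config.generations + 1):
        if U > 0 and m < N:
            m += rng.binomial(N - m, U)
        if 0 < m < N:
            w = m * (1.0 - s)
            m = int(rng.binomial(N, w / (w + (N - m))))
        traj[g] = m / N
    return traj


@dataclass(frozen=True)
class RecoveryReport:
    """Bias and interval coverage of the rate estimator over simulated MAs."""

    true_U: float
    n_experiments: int
    n_lines: int
    t_gens: int
    alpha: float
    mean_k: float
    se_k: float
    mean_point_estimate: float
    ci_coverage: float
    k_distribution: dict[int, int]


def recover_U(
    n_experiments: int,
    true_U: float,
    n_lines: int,
    t_gens: int,
    alpha: float = 0.05,
    seed: int | None = None,
    design: AssayDesign | None = None,
) -> RecoveryReport:
    """End-to-end parameter recovery of the Mrt mutation rate.

    For each experiment: simulate an MA + assay with
    :func:`~mrtline.synthetic_data.generate_ma_experiment`, classify the
    table, take ``k`` = number of lines classified strong Mrt, and compute
    the point estimate and exact interval.  Coverage is the fraction of
    experiments whose interval contains ``true_U`` (the exact Poisson
    interval is conservative, so coverage should be at least 1 - alpha).
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    horizon = design.assay_generations if design else None
    root = np.random.SeedSequence(seed)
    ks, points, covered = [], [], 0
    for child in root.spawn(n_experiments):
        table, _ = generate_ma_experiment(n_lines, t_gens, true_U, design=design, seed=child)
        _, counts = classify_table(
            table, horizon=horizon if horizon is not None else 21
        )
        k = counts[MrtClass.STRONG.value]
        est = rate_estimation.rate_ci(
            rate_estimation.MutationCountData(k=k, n=n_lines, t=t_gens), alpha=alpha
        )
        ks.append(k)
        points.append(est.U)
        if est.U_low <= true_U <= est.U_high:
            covered += 1
    ks_arr = np.asarray(ks, dtype=float)
    return RecoveryReport(
        true_U=true_U,
        n_experiments=n_experiments,
        n_lines=n_lines,
        t_gens=t_gens,
        alpha=alpha,
        mean_k=float(ks_arr.mean()),
        se_k=float(ks_arr.std(ddof=1) / np.sqrt(n_experiments)) if n_experiments > 1 else 0.0,
        mean_point_estimate=float(np.mean(points)),
        ci_coverage=covered / n_experiments,
        k_distribution=dict(sorted(Counter(ks).items())),
    )
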