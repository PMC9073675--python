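"""Mutation–selection-balance (MSB) inference for a selfing population.

For a highly selfing species such as *C. elegans*, a deleterious allele at
MSB sits at equilibrium frequency ``q ≈ mu/s``, where ``mu`` is the
wild-type→mutant mutation rate and ``s`` the homozygous selection
coefficient.  Summed over all loci capable of producing a phenotype, the
phenotype frequency at MSB is approximately ``U/s_bar`` with ``U`` the
genome-wide mutation rate to the phenotype.  Inverting this gives
``s = U/q_hat`` — a selection coefficient inferred from the phenotype
frequency in a sample of wild isolates and an independently measured ``U``.

The deterministic recursion :func:`msb_recursion` checks the approximation:
it models the population as fully homozygous selfing lineages, applying in
each generation irreversible mutation ``q -> q + U(1-q)`` followed by
selection ``q -> q(1-s) / (1 - s q)``, and iterates to its fixed point.  For
``U << s`` the fixed point is ``U/s`` up to terms of order ``U``.

When the sampled phenotype count is itself a lower bound ("at least 6 of 95
isolates"), the inferred ``s`` is an upper bound; callers should report it
with one-sided semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FrequencyEstimate",
    "SelectionInference",
    "RecursionResult",
    "s_from_frequency",
    "frequency_with_ci",
    "msb_recursion",
]


@dataclass(frozen=True)
class FrequencyEstimate:
    """Sample phenotype frequency with an exact (Clopper–Pearson) interval."""

    count: int
    total: int
    q_hat: float
    q_low: float
    q_high: float
    alpha: float


@dataclass(frozen=True)
class SelectionInference:
    """Selection coefficient inferred from MSB: ``s_hat = U / q_hat``."""

    U: float
    q_hat: float
    s_hat: float

    @classmethod
    def from_frequency(cls, U: float, q_hat: float) -> "SelectionInference":
        return cls(U=U, q_hat=q_hat, s_hat=s_from_frequency(U, q_hat))


@dataclass(frozen=True)
class RecursionResult:
    """Fixed point of the selfing mutation–selection recursion."""

    q_star: float
    iterations: int
    converged: bool
    U: float
    s: float

    @property
    def msb_approximation(self) -> float:
        """First-order equilibrium ``U/s`` for comparison."""
        return self.U / self.s if self.s > 0 else float("nan")


def s_from_frequency(U: float, q_hat: float) -> float:
    """Selection coefficient ``s = U / q_hat`` under mutation–selection balance.

    Raises for ``q_hat = 0``: with no carriers observed the equation is
    uninformative; use the one-sided upper bound on ``U`` (zero-count
    Poisson interval) instead.
    """
    if U < 0:
        raise ValueError("U must be >= 0")
    if not 0 < q_hat <= 1:
        raise ValueError(
            "q_hat must be in (0, 1]; for a zero observed frequency the MSB "
            "relation is uninformative — report the one-sided bound on U instead"
        )
    return U / q_hat


def frequency_with_ci(count: int, total: int, alpha: float = 0.05) -> FrequencyEstimate:
    """Sample frequency ``count/total`` with an exact binomial interval."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= count <= total:
        raise ValueError("count must be in [0, total]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    low, high = proportion_confint(count, total, alpha=alpha, method="beta")
    # Clopper–Pearson endpoints degenerate cleanly at the boundaries.
    low = 0.0 if count == 0 else float(low)
    high = 1.0 if count == total else float(high)
    return FrequencyEstimate(
        count=count, total=total, q_hat=count / total, q_low=low, q_high=high, alpha=alpha
    )


def msb_recursion(
    U: float,
    s: float,
    q0: float = 0.0,
    tol: float = 1e-12,
    max_iters: int = 10**6,
) -> RecursionResult:
    """Iterate the fully selfing mutation–selection recursion to equilibrium.

    Each generation applies irreversible mutation ``q -> q + U(1-q)`` and
    then selection ``q -> q(1-s)/(1 - s q)`` (relative fitness 1 vs 1-s
    among homozygous selfing lineages).  Iteration stops when the relative
    change per generation drops below ``tol``; failure to converge within
    ``max_iters`` is flagged, not raised.
    """
    if not 0 <= q0 <= 1:
        raise ValueError("q0 must be in [0, 1]")
    if U < 0 or U > 1:
        raise ValueError("U must be in [0, 1]")
    if not 0 <= s < 1:
        raise ValueError("s must be in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")

    q = float(q0)
    for it in range(1, max_iters + 1):
        q_mut = q + U * (1.0 - q)
        q_next = q_mut * (1.0 - s) / (1.0 - s * q_mut)
        delta = abs(q_next - q)
        q = q_next
        if delta == 0.0 or delta < tol * max(q, 1e-300):
            return RecursionResult(q_star=q, iterations=it, converged=True, U=U, s=s)
    return RecursionResult(q_star=q, iterations=max_iters, converged=False, U=U, s=s)
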