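"""Genome-wide Mrt mutation-rate estimation with exact Poisson intervals.

The mutation-accumulation (MA) design observes ``k`` phenotype-changing
mutations in ``n`` lines propagated for ``t`` generations, i.e. ``n*t``
meioses.  The point estimate of the genomic rate is ``U = k/(n*t)`` per
genome per generation.  This is the haploid-rate convention: mutations arise
in diploids at rate 2U, but a new neutral heterozygous mutation is lost from
a single-descent MA line with probability 1/2, and the two factors cancel.

The confidence interval treats ``k`` as a Poisson count and uses the exact
(Garwood) interval via the chi-square identity: ``2*lambda_low`` is the
``alpha/2`` fractile of a chi-square with ``2k`` degrees of freedom
(``lambda_low = 0`` when ``k = 0``), and ``2*lambda_high`` the ``1-alpha/2``
fractile with ``2(k+1)`` df.  Dividing the count bounds by the number of
meioses gives the rate bounds.

Dividing ``U`` by a per-nucleotide mutation rate converts the genomic rate
into a mutational-target size in base pairs (the aggregate length of
sequence at which a hit produces the phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "MutationCountData",
    "RateEstimate",
    "TargetSizeEstimate",
    "point_rate",
    "poisson_exact_ci",
    "rate_ci",
    "target_size",
    "ELEGANS_SITE_RATE",
    "ELEGANS_GENOME_SIZE",
]

#: Per-nucleotide mutation rate per generation measured in these MA lines.
ELEGANS_SITE_RATE = 2.8e-9
#: Approximate C. elegans genome size in base pairs.
ELEGANS_GENOME_SIZE = 1e8


@dataclass(frozen=True)
class MutationCountData:
    """Observed mutation count in an MA experiment: ``k`` hits in ``n*t`` meioses."""

    k: int
    n: int
    t: int

    def __post_init__(self) -> None:
        if self.n < 1 or self.t < 1:
            raise ValueError("n and t must be >= 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.k > self.n:
            raise ValueError("k cannot exceed the number of lines n")

    @property
    def meioses(self) -> int:
        """Total line-generations of MA propagation, ``n*t``."""
        return self.n * self.t


@dataclass(frozen=True)
class RateEstimate:
    """Point and exact-interval estimate of a genomic mutation rate."""

    U: float
    lambda_low: float
    lambda_high: float
    U_low: float
    U_high: float
    alpha: float
    meioses: int


@dataclass(frozen=True)
class TargetSizeEstimate:
    """Mutational-target size implied by a genomic rate.

    ``n_sites = U / mu_site`` is the number of nucleotides at which a
    mutation yields the phenotype; ``fraction`` expresses it relative to the
    genome size.
    """

    U: float
    mu_site: float
    genome_size: float
    n_sites: float
    fraction: float


def point_rate(data: MutationCountData) -> float:
    """Point estimate ``U = k/(n*t)`` per genome per generation."""
    return data.k / data.meioses


def poisson_exact_ci(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided confidence bounds for a Poisson mean given count ``k``.

    Uses the chi-square fractile form of the Garwood interval; the lower
    bound is 0 when ``k = 0`` (the 0-df chi-square degenerates), matching
    the one-sided use of the interval for an observed zero count.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 0:
        raise ValueError("k must be >= 0")
    lam_low = 0.0 if k == 0 else float(stats.chi2.ppf(alpha / 2, 2 * k)) / 2.0
    lam_high = float(stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1))) / 2.0
    return lam_low, lam_high


def rate_ci(data: MutationCountData, alpha: float = 0.05) -> RateEstimate:
    """Exact Poisson confidence interval on the genomic rate ``U = k/(n*t)``."""
    lam_low, lam_high = poisson_exact_ci(data.k, alpha)
    m = data.meioses
    return RateEstimate(
        U=point_rate(data),
        lambda_low=lam_low,
        lambda_high=lam_high,
        U_low=lam_low / m,
        U_high=lam_high / m,
        alpha=alpha,
        meioses=m,
    )


def target_size(
    U: float,
    mu_site: float = ELEGANS_SITE_RATE,
    genome_size: float = ELEGANS_GENOME_SIZE,
) -> TargetSizeEstimate:
    """Mutational-target size ``U / mu_site`` and its genome fraction."""
    if U < 0:
        raise ValueError("U must be >= 0")
    if mu_site <= 0 or genome_size <= 0:
        raise ValueError("mu_site and genome_size must be positive")
    n_sites = U / mu_site
    return TargetSizeEstimate(
        U=U,
        mu_site=mu_site,
        genome_size=genome_size,
        n_sites=n_sites,
        fraction=n_sites / genome_size,
    )
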