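"""Independent oracles used by the test suite.

These deliberately avoid the production code paths: the Poisson interval is
solved by numeric root-finding on the Poisson tail sums themselves, and the
Clopper–Pearson interval comes straight from beta quantiles.
"""

from __future__ import annotations

from scipy import optimize, stats


def poisson_ci_bruteforce(k: int, alpha: float) -> tuple[float, float]:
    """Solve the defining tail-sum equations of the exact Poisson interval.

    Lower bound: the lambda with P(X >= k) = alpha/2; upper bound: the
    lambda with P(X <= k) = alpha/2, X ~ Poisson(lambda).  Solved by brentq
    on scipy's Poisson tail probabilities; the lower bound is 0 for k = 0.
    """
    hi_bracket = 10.0 * (k + 10)
    if k == 0:
        low = 0.0
    else:
        # P(X >= k) = sf(k - 1); increasing in lambda
        low = optimize.brentq(
            lambda lam: stats.poisson.sf(k - 1, lam) - alpha / 2, 1e-12, hi_bracket,
            xtol=1e-14, rtol=1e-15,
        )
    high = optimize.brentq(
        lambda lam: stats.poisson.cdf(k, lam) - alpha / 2, 1e-12, hi_bracket,
        xtol=1e-14, rtol=1e-15,
    )
    return low, high


def clopper_pearson_bruteforce(count: int, total: int, alpha: float) -> tuple[float, float]:
    """Clopper–Pearson interval directly from beta quantiles."""
    low = 0.0 if count == 0 else float(stats.beta.ppf(alpha / 2, count, total - count + 1))
    high = 1.0 if count == total else float(stats.beta.ppf(1 - alpha / 2, count + 1, total - count))
    return low, high
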