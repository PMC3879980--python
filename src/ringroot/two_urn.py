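"""The two-urn hypergeometric rooting test, in log space.

The question the test answers: a gene family's sequences are split between
the two sides of a candidate root ("urns").  If the family really
originated on one side, the split should be lopsided; if the asymmetry
could be sampling noise, the root placement has no support.  The null is
sampling without replacement — a hypergeometric distribution — with the
two urns assumed to be equal samples of n = N/2 sequences each, K marked
sequences (the members of the two contrasted groups) distributed between
them, and x_obs the marked count observed in the larger urn.

Everything is carried in natural-log space (a stable ratio recurrence for
the mass, log-sum-exp for tails) so two-sided probabilities of order
1e-200 are accurate and representable; results are reported as
(log10 p, p) pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

__all__ = ["TwoUrnTest", "LOG_ZERO", "log_pmf", "log_upper_tail", "two_sided_p", "root_side_test"]

#: Sentinel for log(0), returned for x outside the feasible range.
LOG_ZERO = -math.inf


@dataclass(frozen=True)
class TwoUrnTest:
    """A fully populated two-urn test result.

    Attributes
    ----------
    N, K, n, x_obs:
        Population size, marked count, per-urn sample size, and the marked
        count observed in the larger urn.
    log_p_upper:
        Natural log of the upper tail P(X >= x_obs).
    log_p_two_sided:
        Natural log of the two-sided probability (capped at log 1 = 0).
    side:
        ``"side1"`` or ``"side2"``: which input count is the larger one
        (the side the gain site is inferred to be on), or ``"tie"``.
    """

    N: int
    K: int
    n: int
    x_obs: int
    log_p_upper: float
    log_p_two_sided: float
    side: str = ""

    @property
    def p_two_sided(self) -> float:
        return math.exp(self.log_p_two_sided)

    @property
    def log10_p(self) -> float:
        return self.log_p_two_sided / math.log(10)


def _check_params(N: int, K: int, n: int) -> None:
    if N < 1:
        raise ValueError("population size N must be >= 1")
    if not 0 <= K <= N:
        raise ValueError(f"marked count K={K} outside [0, {N}]")
    if not 0 <= n <= N:
        raise ValueError(f"sample size n={n} outside [0, {N}]")


def log_pmf(N: int, K: int, n: int, x: int) -> float:
    """log of the hypergeometric mass C(K,x) C(N-K,n-x) / C(N,n).

    Evaluated over the whole support at once: relative masses come from
    the exact ratio recurrence
    ``pmf(x+1)/pmf(x) = (K-x)(n-x) / ((x+1)(N-K-n+x+1))``
    accumulated in log space, and the normalizer from log-sum-exp.  This
    avoids the cancellation of three huge log-gamma terms, so the pmf sums
    to 1 at machine precision while staying finite for tails far below the
    double-precision underflow threshold.  Returns :data:`LOG_ZERO` for x
    outside the feasible range [max(0, n+K-N), min(n, K)].
    """
    _check_params(N, K, n)
    lo = max(0, n + K - N)
    if x < lo or x > min(n, K):
        return LOG_ZERO
    _, lp = _log_pmf_support(N, K, n)
    return float(lp[x - lo])


@lru_cache(maxsize=128)
def _log_pmf_support(N: int, K: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log-pmf arrays, normalized in log space."""
    xs = np.arange(max(0, n + K - N), min(n, K) + 1)
    if len(xs) == 1:
        return xs, np.zeros(1)
    x = xs[:-1].astype(float)
    ratios = (
        np.log(K - x) + np.log(n - x) - np.log(x + 1) - np.log(N - K - n + x + 1)
    )
    raw = np.concatenate([[0.0], np.cumsum(ratios)])
    lp = raw - logsumexp(raw)
    return xs, lp


def log_upper_tail(N: int, K: int, n: int, x_obs: int) -> float:
    """log P(X >= x_obs) via log-sum-exp over the support."""
    _check_params(N, K, n)
    xs, lp = _log_pmf_support(N, K, n)
    mask = xs >= x_obs
    if not mask.any():
        return LOG_ZERO
    return float(logsumexp(lp[mask]))


def two_sided_p(N: int, K: int, n: int, x_obs: int) -> float:
    """Natural-log two-sided probability of a split at least this extreme.

    For the equal-urn design (n = N/2) the distribution is symmetric about
    K/2, so the two-sided probability is twice the upper tail when
    x_obs > K/2 — exactly the sum P(X >= x_obs) + P(X <= K - x_obs).  At or
    below the center the whole distribution is covered and p = 1.  For
    unequal urns (not the standard design) the method sums the mass of all
    outcomes no more probable than x_obs.

    Returns the natural log of p, capped at 0 (p = 1).
    """
    _check_params(N, K, n)
    if 2 * n == N:
        if 2 * x_obs <= K:
            return 0.0
        lp = math.log(2) + log_upper_tail(N, K, n, x_obs)
        return min(lp, 0.0)
    # general (unequal-urn) definition: sum pmf(x) <= pmf(x_obs)
    xs, lps = _log_pmf_support(N, K, n)
    obs = log_pmf(N, K, n, x_obs)
    if obs == LOG_ZERO:
        raise ValueError(f"x_obs={x_obs} outside the feasible range")
    mask = lps <= obs + 1e-12
    return min(float(logsumexp(lps[mask])), 0.0)


def root_side_test(
    count_side1: int,
    count_side2: int,
    N_total: int,
    *,
    allow_odd: bool = False,
) -> TwoUrnTest:
    """Build the two-urn test for a gene flow split across a root.

    Parameters
    ----------
    count_side1, count_side2:
        Marked sequence counts on the two sides of the candidate root.
    N_total:
        Total population of sequences; both urns are assumed equal samples
        of n = N_total/2.
    allow_odd:
        Odd populations are rejected by default because the equal-urn
        design needs n = N/2 exactly; with ``allow_odd`` the sample size is
        floored (with a warning).
    """
    if count_side1 < 0 or count_side2 < 0:
        raise ValueError("counts must be non-negative")
    if count_side1 + count_side2 > N_total:
        raise ValueError("counts exceed the population size")
    if N_total % 2:
        if not allow_odd:
            raise ValueError(
                "odd population: the equal-urn design needs n = N/2 "
                "(pass allow_odd=True to floor it)"
            )
        warnings.warn("odd population; flooring the per-urn sample size")
    n = N_total // 2
    K = count_side1 + count_side2
    x_obs = max(count_side1, count_side2)
    log_two = two_sided_p(N_total, K, n, x_obs)
    if count_side1 > count_side2:
        side = "side1"
    elif count_side2 > count_side1:
        side = "side2"
    else:
        side = "tie"
    return TwoUrnTest(
        N=N_total,
        K=K,
        n=n,
        x_obs=x_obs,
        log_p_upper=log_upper_tail(N_total, K, n, x_obs),
        log_p_two_sided=log_two,
        side=side,
    )
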