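"""Independent oracles used by the tests.

These deliberately avoid the package's own ROC/SDT code paths: concordance
is computed by exhaustive pair enumeration, and expected rating-ROC areas by
direct normal-CDF arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm


def concordance(signal_scores, noise_scores) -> float:
    """Ties-adjusted Mann-Whitney statistic by brute force over all pairs."""
    total = 0.0
    for s in signal_scores:
        for n in noise_scores:
            if s > n:
                total += 1.0
            elif s == n:
                total += 0.5
    return total / (len(signal_scores) * len(noise_scores))


def type1_ordinal_scores(resp_a, conf):
    """8-level ordinal score: higher = more confident the alternative was A."""
    return [int(c) if ra else -int(c) for ra, c in zip(resp_a, conf)]


def folded_mixture_quartiles(M: float, sigma: float) -> np.ndarray:
    """Population 25/50/75th percentiles of |X|, X ~ 0.5 N(M/2, s) + 0.5 N(-M/2, s)."""

    def cdf(x):
        return norm.cdf((x - M / 2) / sigma) + norm.cdf((x + M / 2) / sigma) - 1.0

    hi = M / 2 + 10 * sigma
    return np.array(
        [brentq(lambda x, q=q: cdf(x) - q, 0.0, hi) for q in (0.25, 0.5, 0.75)]
    )


def expected_type1_rating_auc(M: float, sigma: float) -> float:
    """Population 8-category trapezoidal Type-I AUC of the single-stage model.

    With confidence cut at the population quartiles q1 < q2 < q3 of the
    pooled folded distribution, the ordered response categories correspond to
    internal-response intervals with cut points
    (+inf, q3, q2, q1, 0, -q1, -q2, -q3, -inf); the ROC points are the
    category CDFs of N(+M/2, s) (signal) and N(-M/2, s) (noise).
    """
    q1, q2, q3 = folded_mixture_quartiles(M, sigma)
    cuts = np.array([q3, q2, q1, 0.0, -q1, -q2, -q3])
    # cumulative P(internal > cut) scanning from the most-A category leftward
    hit = np.concatenate([[0.0], norm.sf((cuts - M / 2) / sigma), [1.0]])
    fa = np.concatenate([[0.0], norm.sf((cuts + M / 2) / sigma), [1.0]])
    return float(np.trapezoid(hit, fa))
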