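"""Independent estimation oracles used by the tests.

Deliberately does not share code paths with :mod:`ppx.estimation`: the
log-likelihood is evaluated from the raw exposure matrix via logsumexp,
and the maximizer is a dense grid search refined by bisection on the
analytic score (the conditional log-likelihood is concave, so the score is
monotone decreasing and bisection is exact).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, softmax


def loglik(beta: float, sets: np.ndarray) -> float:
    x = np.asarray(sets, dtype=float)
    return float(np.sum(beta * x[:, 0] - logsumexp(beta * x, axis=1)))


def score(beta: float, sets: np.ndarray) -> float:
    x = np.asarray(sets, dtype=float)
    w = softmax(beta * x, axis=1)
    return float(np.sum(x[:, 0] - np.sum(w * x, axis=1)))


def brute_force_beta(sets, lo=-10.0, hi=10.0, grid_points=2001) -> float:
    """Grid search over beta, then bisection on the score."""
    grid = np.linspace(lo, hi, grid_points)
    vals = [loglik(b, sets) for b in grid]
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_points - 1)]
    sa, sb = score(a, sets), score(b, sets)
    if sa < 0 or sb > 0:  # maximum at the bracket edge; widen once
        a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        if score(mid, sets) > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def statsmodels_fit(sets):
    """(beta, se) from the established conditional-logit implementation."""
    from statsmodels.discrete.conditional_models import ConditionalLogit

    x = np.asarray(sets, dtype=float)
    n, periods = x.shape
    groups = np.repeat(np.arange(n), periods)
    endog = np.tile([1] + [0] * (periods - 1), n)
    res = ConditionalLogit(endog, x.reshape(-1, 1), groups=groups).fit(
        disp=0, method="newton", tol=1e-12)
    return float(res.params[0]), float(res.bse[0])


def random_matched_sets(rng, min_sets=5, max_sets=30):
    """A random informative, non-degenerate matched-set collection.

    Mixes sparse and dense exposure probabilities so concordant and
    doubly-exposed sets occur; retries until the instance has a finite,
    interior MLE (some case-period and some control-period exposure among
    the informative sets).
    """
    while True:
        n = int(rng.integers(min_sets, max_sets + 1))
        m = int(rng.integers(1, 7))
        p = rng.uniform(0.05, 0.6)
        sets = (rng.uniform(size=(n, 1 + m)) < p).astype(np.int8)
        tot = sets.sum(axis=1)
        informative = (tot > 0) & (tot < 1 + m)
        y = sets[informative, 0]
        if informative.sum() >= 2 and 0 < y.sum() < informative.sum():
            return sets
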