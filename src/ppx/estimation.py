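"""Conditional-likelihood estimation for 1:M matched binary exposure.

For matched set *i* with exposure indicators ``x_i0`` (case period) and
``x_i1..x_iM`` (control periods), the conditional log-likelihood of the
log odds ratio beta is

    l(beta) = sum_i [ beta * x_i0 - log( sum_j exp(beta * x_ij) ) ].

With binary exposure each set enters only through ``(x_i0, m_i)`` where
``m_i`` is its number of exposed periods, so the likelihood collapses to a
handful of patterns:

    l_i(beta) = beta * x_i0 - log( m_i * exp(beta) + (1 + M - m_i) ).

Sets with all-zero or all-one exposure are concordant and carry no
information; they are dropped with a logged count.  The maximizer uses
safeguarded Newton iteration (step-halving on the log-likelihood) from
beta = 0 and converges when the score falls below 1e-10 in magnitude.

When every informative set has exactly one exposed period the MLE has the
closed form exp(beta) = M * a / b with standard error sqrt(1/a + 1/b),
where ``a`` counts case-exposed sets and ``b`` exposed control indicators;
:func:`closed_form_or` implements it and serves as an internal cross-check.

Reported quantities follow the convention of administrative-claims tables:
*truncation* (not rounding) to one decimal place, full precision retained
internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateEstimateError, EstimationError

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "IntervalResult", "fit_conditional_logit",
           "closed_form_or", "wald_ci", "event_rate", "truncate1",
           "sets_from_counts"]

_SCORE_TOL = 1e-10
_MAX_ITER = 100


@dataclass(frozen=True)
class FitResult:
    """Conditional-logit fit: log-OR, its standard error, bookkeeping."""

    beta: float
    se: float
    n_sets: int
    n_informative: int
    n_dropped: int
    n_iter: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass(frozen=True)
class IntervalResult:
    """Per-window output row: counts, rate, OR with 95% CI.

    ``or_hat``, ``ci_low``, ``ci_high`` are full precision; the reported
    (truncated) forms are produced at table-emission time.  ``flag`` is
    empty for a regular estimate, else one of ``"no-discordant"``,
    ``"infinite-OR"``, ``"zero-OR"``.
    """

    label: str
    a: int
    b: int
    mean_control: float
    rate_per_100k: float
    or_hat: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    beta_hat: float = float("nan")
    se_beta: float = float("nan")
    flag: str = ""


def _patterns(exposure: np.ndarray):
    """Collapse a (n, 1+M) exposure array to (y, m, count) patterns."""
    exposure = np.asarray(exposure, dtype=np.int64)
    if exposure.ndim != 2 or exposure.shape[1] < 2:
        raise ValueError("exposure must be (n_sets, 1 + M) with M >= 1")
    periods = exposure.shape[1]
    m = exposure.sum(axis=1)
    y = exposure[:, 0]
    informative = (m > 0) & (m < periods)
    n_dropped = int((~informative).sum())
    key = y[informative] * (periods + 1) + m[informative]
    uniq, counts = np.unique(key, return_counts=True)
    ys = uniq // (periods + 1)
    ms = uniq % (periods + 1)
    return ys, ms, counts, periods, n_dropped, exposure.shape[0]


def fit_conditional_logit(sets) -> FitResult:
    """Maximize the matched-set conditional likelihood for binary exposure.

    ``sets`` is an array-like of shape ``(n_sets, 1 + M)`` (column 0 the
    case period) or a :class:`~ppx.crossover.MatchedSets` /
    list of :class:`~ppx.crossover.MatchedSet`.

    Raises
    ------
    EstimationError
        If no set has discordant exposure.
    DegenerateEstimateError
        If the MLE is infinite (exposure only in case periods among
        informative sets) or zero (only in control periods).
    """
    exposure = _as_array(sets)
    ys, ms, counts, periods, n_dropped, n_total = _patterns(exposure)
    if n_dropped:
        logger.info("dropped %d concordant matched set(s) of %d",
                    n_dropped, n_total)
    n_informative = int(counts.sum())
    if n_informative == 0:
        raise EstimationError("no discordant sets")
    case_exposed = counts[ys == 1].sum()
    if case_exposed == n_informative:
        raise DegenerateEstimateError(
            "infinite", "exposure only in case periods: infinite odds ratio")
    if case_exposed == 0:
        raise DegenerateEstimateError(
            "zero", "exposure only in control periods: zero odds ratio")

    r = periods - ms  # unexposed periods per pattern
    log_m, log_r = np.log(ms), np.log(r)

    def loglik(beta):
        return float(np.sum(counts * (beta * ys
                                      - np.logaddexp(log_m + beta, log_r))))

    def score_info(beta):
        p = np.exp(log_m + beta - np.logaddexp(log_m + beta, log_r))
        score = float(np.sum(counts * (ys - p)))
        info = float(np.sum(counts * p * (1.0 - p)))
        return score, info

    beta = 0.0
    ll = loglik(beta)
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        score, info = score_info(beta)
        if abs(score) < _SCORE_TOL:
            break
        step = score / info
        new_beta = beta + step
        new_ll = loglik(new_beta)
        halvings = 0
        while new_ll < ll - 1e-13 and halvings < 50:
            step *= 0.5
            new_beta = beta + step
            new_ll = loglik(new_beta)
            halvings += 1
        beta, ll = new_beta, new_ll
    _, info = score_info(beta)
    return FitResult(beta=beta, se=1.0 / math.sqrt(info),
                     n_sets=n_total, n_informative=n_informative,
                     n_dropped=n_dropped, n_iter=n_iter)


def _as_array(sets) -> np.ndarray:
    if hasattr(sets, "exposure"):
        return np.asarray(sets.exposure)
    sets = list(sets) if not isinstance(sets, np.ndarray) else sets
    if isinstance(sets, list) and sets and hasattr(sets[0], "case_exposed"):
        return np.asarray([[s.case_exposed, *s.control_exposed] for s in sets])
    return np.asarray(sets)


def sets_from_counts(a: int, b: int, M: int) -> np.ndarray:
    """Reconstruct a minimal matched-set array from summary counts.

    ``a`` sets exposed in the case period only and ``b`` sets exposed in
    exactly one of the ``M`` control periods (spread round-robin; the
    conditional likelihood depends only on the per-set exposure totals).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    out = np.zeros((a + b, 1 + M), dtype=np.int8)
    out[:a, 0] = 1
    for i in range(b):
        out[a + i, 1 + (i % M)] = 1
    return out


def closed_form_or(a: int, b: int, M: int) -> tuple[float, float]:
    """Analytic 1:M matched-pair estimate when all sets are single-exposure.

    Maximizing ``a*beta - (a+b) * log(exp(beta) + M)`` gives
    ``exp(beta) = M * a / b``; the observed-information standard error of
    beta is ``sqrt(1/a + 1/b)``.  Returns ``(odds_ratio, se_beta)``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if a <= 0 or b <= 0:
        raise DegenerateEstimateError(
            "infinite" if b <= 0 else "zero",
            "closed form requires a > 0 and b > 0")
    return M * a / b, math.sqrt(1.0 / a + 1.0 / b)


def wald_ci(beta_hat: float, se_beta: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval on the OR scale: exp(beta -/+ z * se)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if se_beta <= 0:
        if se_beta == 0:
            return math.exp(beta_hat), math.exp(beta_hat)
        raise ValueError("se_beta must be >= 0")
    z = norm.ppf(0.5 + level / 2.0)
    return math.exp(beta_hat - z * se_beta), math.exp(beta_hat + z * se_beta)


def event_rate(n_events: int, n_deliveries: int) -> float:
    """Events per 100,000 deliveries, truncated to one decimal place."""
    if n_deliveries <= 0:
        raise ValueError("n_deliveries must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return truncate1(100_000.0 * n_events / n_deliveries)


def truncate1(x: float) -> float:
    """Truncate a nonnegative value to one decimal place (floor, not round).

    A guard of 1e-8 absorbs float representation error so that a value
    that is mathematically, say, 14.0 but stored as 13.999999999 is not
    pushed down a decimal.
    """
    if not math.isfinite(x):
        raise ValueError("x must be finite")
    if x < 0:
        raise ValueError("x must be >= 0")
    return math.floor(10.0 * x + 1e-8) / 10.0
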