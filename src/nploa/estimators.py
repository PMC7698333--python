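"""Nonparametric quantile estimators for paired-difference samples.

All six estimators are L-statistics: linear combinations ``sum_i W_i X(i)``
of the order statistics ``X(1) <= ... <= X(n)`` with weights that depend only
on the sample size ``n`` and the target level ``p``.  Exposing the weight
vectors directly (``quantile_weights``) lets the Monte-Carlo engine evaluate
an estimator on thousands of sorted samples with a single matrix product.

Estimators
----------
``sq``
    Sample quantile: linear interpolation of the two order statistics
    bracketing rank ``p(n+1)``.  Undefined when ``p(n+1)`` falls outside
    ``[1, n]`` — at the limits-of-agreement levels (0.025, 0.975) this
    requires ``n >= 39``.
``hd``
    Harrell–Davis: weights are increments of the regularized incomplete beta
    function ``I_x(p(n+1), (1-p)(n+1))`` over the uniform partition ``i/n``.
``bp``
    Bernstein polynomial: binomial point masses ``B(i-1; n-1, p)``.
``hdlc``
    Harrell–Davis on a level-crossing empirical distribution: as ``hd`` but
    the partition is the cumulative sum of re-weighted empirical masses that
    give the extreme observations less weight than 1/n.
``sv``
    Sfakianakis–Verginis (first of their three estimators): binomial weights
    with boundary corrections designed for tail quantiles at small n.
``no``
    Navruz–Özdemir: binomial weights blended between adjacent order
    statistics, again with boundary corrections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import special, stats

__all__ = [
    "ESTIMATOR_IDS",
    "CrossedLimitsWarning",
    "SampleTooSmallError",
    "OrderedSample",
    "LevelCrossingWeights",
    "LoAPair",
    "sq_quantile",
    "hd_weights",
    "hd_quantile",
    "bp_quantile",
    "lc_weights",
    "hdlc_quantile",
    "sv_quantile",
    "no_quantile",
    "quantile_weights",
    "estimate_loa",
    "min_sample_size",
]

#: Identifiers of the six nonparametric estimators, in canonical order.
ESTIMATOR_IDS = ("sq", "hd", "bp", "hdlc", "sv", "no")

#: Quantile levels of the lower and upper limit of agreement.
LOA_LEVELS = (0.025, 0.975)


class SampleTooSmallError(ValueError):
    """The sample is too small for the requested estimator/level."""


class CrossedLimitsWarning(UserWarning):
    """Estimated lower limit of agreement exceeds the upper limit."""


class OrderedSample:
    """A sorted vector of paired differences.

    Parameters
    ----------
    values : array-like
        Finite real values; sorted ascending on construction.
    """

    __slots__ = ("values", "n")

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("sample must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample contains non-finite values")
        self.values = np.sort(arr)
        self.n = int(arr.size)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OrderedSample(n={self.n})"


class LevelCrossingWeights(NamedTuple):
    """Level-crossing empirical masses ``w`` and their cumulative sums ``q``."""

    w: np.ndarray
    q: np.ndarray


@dataclass(frozen=True)
class LoAPair:
    """Lower/upper limits of agreement with estimator provenance.

    ``bias`` (the mean paired difference) is only populated by the classical
    parametric analysis; nonparametric estimators leave it ``None``.
    """

    lower: float
    upper: float
    estimator_id: str
    bias: float | None = None


def _check_p(p: float) -> float:
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must lie in (0, 1), got {p}")
    return p


def _as_sample(sample) -> OrderedSample:
    return sample if isinstance(sample, OrderedSample) else OrderedSample(sample)


# ---------------------------------------------------------------------------
# weight constructions


def sq_weights(n: int, p: float) -> np.ndarray:
    """Sample-quantile weights: mass split between ranks r and r+1.

    With ``h = p(n+1)``, ``r = floor(h)`` and ``alpha = h - r``, the weight
    vector puts ``1 - alpha`` on X(r) and ``alpha`` on X(r+1).  Requires
    ``1 <= h <= n`` so that both ranks exist.
    """
    p = _check_p(p)
    h = p * (n + 1)
    if h < 1.0 or h > n:
        raise SampleTooSmallError(
            f"sample quantile at p={p} needs p(n+1) in [1, n]; "
            f"n={n} gives p(n+1)={h:.4g} (minimum n is {min_sample_size('sq', p, p)})"
        )
    r = int(math.floor(h))
    alpha = h - r
    w = np.zeros(n)
    w[r - 1] = 1.0 - alpha
    if alpha > 0.0:
        w[r] = alpha
    return w


def hd_weights(n: int, p: float) -> np.ndarray:
    """Harrell–Davis weights.

    ``W_i = I_{i/n}(a, b) - I_{(i-1)/n}(a, b)`` with ``a = p(n+1)``,
    ``b = (1-p)(n+1)`` and ``I`` the regularized incomplete beta function
    (the Beta(a, b) CDF), so the weights telescope to exactly 1.
    """
    p = _check_p(p)
    if n < 1:
        raise ValueError("n must be positive")
    a = p * (n + 1)
    b = (1.0 - p) * (n + 1)
    edges = np.arange(n + 1, dtype=float) / n
    return np.diff(special.betainc(a, b, edges))


def bp_weights(n: int, p: float) -> np.ndarray:
    """Bernstein-polynomial weights: binomial pmf B(i-1; n-1, p), i=1..n."""
    p = _check_p(p)
    if n < 1:
        raise ValueError("n must be positive")
    return stats.binom.pmf(np.arange(n), n - 1, p)


def lc_weights(n: int) -> LevelCrossingWeights:
    """Level-crossing empirical-distribution masses.

    Boundary observations get ``(1/2)(1 - (n-2)/sqrt(n(n-1)))`` each,
    interior observations ``1/sqrt(n(n-1))``; the masses sum to 1 exactly
    (``2 w_1 + (n-2) w_interior = 1`` algebraically).
    """
    if n < 2:
        raise ValueError(f"level-crossing weights need n >= 2, got {n}")
    s = math.sqrt(n * (n - 1.0))
    w = np.full(n, 1.0 / s)
    w[0] = w[-1] = 0.5 * (1.0 - (n - 2.0) / s)
    q = np.cumsum(w)
    q[-1] = 1.0  # exact by construction; kill rounding residue
    return LevelCrossingWeights(w=w, q=q)


def hdlc_weights(n: int, p: float) -> np.ndarray:
    """Harrell–Davis weights over the level-crossing partition q_0=0,q_1..q_n."""
    p = _check_p(p)
    q = lc_weights(n).q
    a = p * (n + 1)
    b = (1.0 - p) * (n + 1)
    edges = np.concatenate(([0.0], q))
    return np.diff(special.betainc(a, b, edges))


def sv_weights(n: int, p: float) -> np.ndarray:
    """Sfakianakis–Verginis (SV1) weights.

    Interior order statistics X(i), i=2..n-1 receive the average of the two
    adjacent binomial probabilities, (B(i)+B(i-1))/2; the three smallest and
    three largest order statistics carry boundary corrections in B(0), B(1),
    B(n-1), B(n).  The corrections cancel so the weights sum to 1 exactly.
    """
    p = _check_p(p)
    if n < 5:
        raise SampleTooSmallError(f"SV estimator needs n >= 5, got {n}")
    b = stats.binom.pmf(np.arange(n + 1), n, p)
    w = np.zeros(n)
    # interior: X(i) for i=2..n-1 (0-based index i-1)
    w[1 : n - 1] += 0.5 * (b[2:n] + b[1 : n - 1])
    w[0] += b[0] + 0.5 * b[1]
    w[1] += 0.5 * b[0]
    w[2] -= 0.5 * b[0]
    w[n - 3] -= 0.5 * b[n]
    w[n - 2] += 0.5 * b[n]
    w[n - 1] += b[n] + 0.5 * b[n - 1]
    return w


def no_weights(n: int, p: float) -> np.ndarray:
    """Navruz–Özdemir weights.

    The bulk term assigns X(i+1), i=1..n-2, the blend
    ``B(i)(1-p) + B(i+1)p``; boundary terms on X(1..3) and X(n-2..n) in
    B(0), B(1), B(n-1), B(n) complete the mass to exactly 1.
    """
    p = _check_p(p)
    if n < 5:
        raise SampleTooSmallError(f"NO estimator needs n >= 5, got {n}")
    b = stats.binom.pmf(np.arange(n + 1), n, p)
    w = np.zeros(n)
    # bulk: X(i+1) for i=1..n-2 (0-based index i)
    w[1 : n - 1] += b[1 : n - 1] * (1.0 - p) + b[2:n] * p
    w[0] += b[0] * 2.0 * p + b[1] * p
    w[1] += b[0] * (2.0 - 3.0 * p)
    w[2] -= b[0] * (1.0 - p)
    w[n - 3] -= b[n] * p
    w[n - 2] += b[n] * (3.0 * p - 1.0)
    w[n - 1] += b[n - 1] * (1.0 - p) + b[n] * (2.0 - 2.0 * p)
    return w


_WEIGHT_FUNCS: dict[str, Callable[[int, float], np.ndarray]] = {
    "sq": sq_weights,
    "hd": hd_weights,
    "bp": bp_weights,
    "hdlc": hdlc_weights,
    "sv": sv_weights,
    "no": no_weights,
}


def quantile_weights(estimator_id: str, n: int, p: float) -> np.ndarray:
    """L-statistic weight vector of the given estimator for (n, p)."""
    try:
        func = _WEIGHT_FUNCS[estimator_id.lower()]
    except KeyError:
        raise ValueError(
            f"unknown estimator {estimator_id!r}; expected one of {ESTIMATOR_IDS}"
        ) from None
    return func(n, p)


def min_sample_size(
    estimator_id: str, p_low: float = LOA_LEVELS[0], p_high: float = LOA_LEVELS[1]
) -> int:
    """Smallest n for which the estimator is defined at both quantile levels.

    For ``sq`` the constraint ``1 <= p(n+1) <= n`` at both tails gives
    n >= 39 at the limits-of-agreement levels; the L-statistic estimators
    only need their structural minimums (hd/bp: 1, hdlc: 2, sv/no: 5,
    classical ba: 2 for a standard deviation).
    """
    est = estimator_id.lower()
    if est == "sq":
        bounds = []
        for p in (p_low, p_high):
            p = _check_p(p)
            bounds.append(math.ceil(1.0 / p - 1.0 - 1e-12))  # p(n+1) >= 1
            bounds.append(math.ceil(p / (1.0 - p) - 1e-12))  # p(n+1) <= n
        return max(1, *bounds)
    fixed = {"hd": 1, "bp": 1, "hdlc": 2, "sv": 5, "no": 5, "ba": 2}
    if est not in fixed:
        raise ValueError(f"unknown estimator {estimator_id!r}")
    return fixed[est]


# ---------------------------------------------------------------------------
# point estimators


def _l_estimate(sample, p: float, estimator_id: str) -> float:
    s = _as_sample(sample)
    w = quantile_weights(estimator_id, s.n, p)
    return float(w @ s.values)


def sq_quantile(sample, p: float) -> float:
    """Sample quantile (1-alpha)X(r) + alpha X(r+1), r = floor(p(n+1))."""
    return _l_estimate(sample, p, "sq")


def hd_quantile(sample, p: float) -> float:
    """Harrell–Davis quantile estimate."""
    return _l_estimate(sample, p, "hd")


def bp_quantile(sample, p: float) -> float:
    """Bernstein-polynomial quantile estimate."""
    return _l_estimate(sample, p, "bp")


def hdlc_quantile(sample, p: float) -> float:
    """Harrell–Davis estimate on the level-crossing empirical distribution."""
    return _l_estimate(sample, p, "hdlc")


def sv_quantile(sample, p: float) -> float:
    """Sfakianakis–Verginis (SV1) quantile estimate."""
    return _l_estimate(sample, p, "sv")


def no_quantile(sample, p: float) -> float:
    """Navruz–Özdemir quantile estimate."""
    return _l_estimate(sample, p, "no")


def estimate_loa(sample, estimator_id: str) -> LoAPair:
    """Limits of agreement: estimator at p=0.025 (lower) and p=0.975 (upper).

    SV and NO carry negative boundary weights, so on pathological samples the
    estimated lower limit can exceed the upper one; this is reported with a
    :class:`CrossedLimitsWarning` and returned as computed so that downstream
    coverage accounting can record it.
    """
    s = _as_sample(sample)
    est = estimator_id.lower()
    lower = _l_estimate(s, LOA_LEVELS[0], est)
    upper = _l_estimate(s, LOA_LEVELS[1], est)
    if lower > upper:
        warnings.warn(
            f"crossed limits of agreement for estimator {est!r}: "
            f"lower={lower:.6g} > upper={upper:.6g}",
            CrossedLimitsWarning,
            stacklevel=2,
        )
    return LoAPair(lower=lower, upper=upper, estimator_id=est)
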