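"""The six study distributions for the coverage simulation.

Each distribution is wrapped in a :class:`DistributionSpec` bundling an exact
CDF, an exact quantile function, and a fast sampler.  The CDF/quantile pair
comes straight from scipy's frozen distributions (never an empirical
approximation), since coverage is defined as F(upper LoA) - F(lower LoA)
under the exact F.  Sampling uses numpy Generator native methods.

The lognormal is ambiguous in its source description: the log-scale mean is
stated as 1 in one place and 0 in another.  The coverage statistic is
invariant to this choice (all estimators are location-scale equivariant and
the lognormal family is a log-location family), but RMSE magnitudes scale by
``e``; the default here is log-mean 0, configurable via ``lognormal_meanlog``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "DISTRIBUTION_NAMES",
    "study_distributions",
    "get_distribution",
    "true_quantile",
]

#: Canonical configuration-file names, in study order.
DISTRIBUTION_NAMES = (
    "normal",
    "lognormal",
    "beta_2_5",
    "beta_2_2",
    "chisq_4",
    "exp_1",
)


@dataclass(frozen=True)
class DistributionSpec:
    """One study distribution: exact CDF/quantile plus a sampler.

    Attributes
    ----------
    name : str
        Canonical identifier (``normal``, ``lognormal``, ``beta_2_5``,
        ``beta_2_2``, ``chisq_4``, ``exp_1``).
    label : str
        Human-readable label for tables and plots.
    params : dict
        Named shape/scale parameters.
    """

    name: str
    label: str
    params: dict
    _frozen: stats.rv_continuous = field(repr=False, compare=False)
    _sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        repr=False, compare=False
    )

    def cdf(self, x):
        """Exact cumulative distribution function F(x)."""
        return self._frozen.cdf(x)

    def quantile(self, p):
        """Exact quantile function (inverse CDF)."""
        return self._frozen.ppf(p)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` iid values using the given generator."""
        return self._sampler(rng, size)


def _make_spec(name: str, lognormal_meanlog: float = 0.0) -> DistributionSpec:
    if name == "normal":
        return DistributionSpec(
            "normal", "Normal(0,1)", {"mean": 0.0, "sd": 1.0},
            stats.norm(),
            lambda rng, size: rng.standard_normal(size),
        )
    if name == "lognormal":
        mu = float(lognormal_meanlog)
        return DistributionSpec(
            "lognormal",
            f"Lognormal({mu:g},1)",
            {"meanlog": mu, "sdlog": 1.0},
            stats.lognorm(s=1.0, scale=math.exp(mu)),
            lambda rng, size: np.exp(mu + rng.standard_normal(size)),
        )
    if name == "beta_2_5":
        return DistributionSpec(
            "beta_2_5", "Beta(2,5)", {"alpha": 2.0, "beta": 5.0, "noncentrality": 0.0},
            stats.beta(2.0, 5.0),
            lambda rng, size: rng.beta(2.0, 5.0, size),
        )
    if name == "beta_2_2":
        return DistributionSpec(
            "beta_2_2", "Beta(2,2)", {"alpha": 2.0, "beta": 2.0, "noncentrality": 0.0},
            stats.beta(2.0, 2.0),
            lambda rng, size: rng.beta(2.0, 2.0, size),
        )
    if name == "chisq_4":
        return DistributionSpec(
            "chisq_4", "Chi-squared(4)", {"df": 4.0},
            stats.chi2(4.0),
            lambda rng, size: rng.chisquare(4.0, size),
        )
    if name == "exp_1":
        return DistributionSpec(
            "exp_1", "Exponential(1)", {"rate": 1.0},
            stats.expon(),
            lambda rng, size: rng.exponential(1.0, size),
        )
    raise ValueError(
        f"unknown distribution {name!r}; expected one of {DISTRIBUTION_NAMES}"
    )


def study_distributions(lognormal_meanlog: float = 0.0) -> list[DistributionSpec]:
    """The six study distributions, in canonical order.

    Normal(0,1); Lognormal(meanlog, 1) with configurable log-mean; Beta(2,5);
    Beta(2,2); Chi-squared(4); Exponential(rate 1).
    """
    return [_make_spec(name, lognormal_meanlog) for name in DISTRIBUTION_NAMES]


def get_distribution(name: str, lognormal_meanlog: float = 0.0) -> DistributionSpec:
    """Look up one study distribution by (case-insensitive) name."""
    return _make_spec(name.strip().lower(), lognormal_meanlog)


def true_quantile(spec: DistributionSpec, p: float) -> float:
    """Exact quantile of a study distribution at level p in (0, 1)."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must lie in (0, 1), got {p}")
    return float(spec.quantile(p))
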