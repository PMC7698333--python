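"""Applied Bland–Altman analysis on paired measurement data.

Two measurement methods applied to the same subjects yield paired
differences d_i = m1_i - m2_i.  The classical limits of agreement are
``mean(d) +/- 1.96 sd(d)``; when the differences are not plausibly normal
(and no transformation or regression fix applies), the 2.5% and 97.5%
quantiles of the differences are estimated nonparametrically with one of the
six L-statistic estimators from :mod:`nploa.estimators`.  Percentile
bootstrap confidence intervals quantify the uncertainty of either limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import (
    LoAPair,
    OrderedSample,
    SampleTooSmallError,
    estimate_loa,
    min_sample_size,
    quantile_weights,
)

__all__ = [
    "PairedData",
    "BootstrapCI",
    "ba_loa",
    "nonparametric_loa",
    "bootstrap_loa_ci",
    "read_paired_data",
]

logger = logging.getLogger(__name__)

#: Conventional Bland–Altman multiplier; exactly 1.96, not a refined quantile.
BA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedData:
    """Paired measurements from two methods on the same subjects.

    Differences follow the convention ``m1 - m2``.  Rows with a missing
    value in either column are dropped at construction (with a logged count):
    a paired analysis needs complete pairs.
    """

    m1: np.ndarray
    m2: np.ndarray
    diffs: np.ndarray
    means: np.ndarray
    n_dropped: int = 0

    @classmethod
    def from_arrays(cls, m1, m2) -> "PairedData":
        m1 = np.asarray(m1, dtype=float).ravel()
        m2 = np.asarray(m2, dtype=float).ravel()
        if m1.size != m2.size:
            raise ValueError(
                f"method vectors differ in length: {m1.size} vs {m2.size}"
            )
        keep = np.isfinite(m1) & np.isfinite(m2)
        n_dropped = int(m1.size - keep.sum())
        if n_dropped:
            logger.info("dropped %d incomplete pairs", n_dropped)
        m1, m2 = m1[keep], m2[keep]
        if m1.size < 2:
            raise ValueError("need at least 2 complete pairs")
        return cls(
            m1=m1, m2=m2, diffs=m1 - m2, means=0.5 * (m1 + m2), n_dropped=n_dropped
        )

    @property
    def n(self) -> int:
        return int(self.diffs.size)


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile-bootstrap confidence intervals for both LoA bounds."""

    ci_lower: tuple[float, float]
    ci_upper: tuple[float, float]
    estimator_id: str
    n_boot: int
    level: float
    seed: int | None
    n_rejected: int = 0  # resamples on which the estimator was undefined


def _clean_diffs(diffs, minimum: int = 2) -> np.ndarray:
    d = np.asarray(diffs, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size < minimum:
        raise SampleTooSmallError(
            f"need at least {minimum} observations, got {d.size}"
        )
    return d


def ba_loa(diffs) -> LoAPair:
    """Classical Bland–Altman limits of agreement.

    bias = mean(d); limits = bias +/- 1.96 * sd(d) with the n-1 denominator.
    """
    d = _clean_diffs(diffs, minimum=2)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = BA_MULTIPLIER * sd
    return LoAPair(lower=bias - half, upper=bias + half, estimator_id="ba", bias=bias)


def nonparametric_loa(diffs, estimator_id: str) -> LoAPair:
    """Nonparametric limits of agreement via the chosen quantile estimator."""
    est = estimator_id.lower()
    if est == "ba":
        return ba_loa(diffs)
    d = _clean_diffs(diffs, minimum=min_sample_size(est))
    return estimate_loa(OrderedSample(d), est)


def bootstrap_loa_ci(
    diffs,
    estimator_id: str,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile-bootstrap confidence intervals for both LoA bounds.

    Differences are resampled with replacement ``n_boot`` times; the limits
    of agreement are recomputed on each resample and the (1-level)/2 and
    1-(1-level)/2 empirical quantiles of the lower and upper limits form the
    two intervals.  Deterministic given ``seed``.

    Because each resample has the same size as the original sample, an
    estimator defined on the data is defined on every resample; the
    ``n_rejected`` count is reported for interface completeness.
    """
    est = estimator_id.lower()
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    d = _clean_diffs(diffs, minimum=min_sample_size(est))
    n = d.size
    rng = np.random.default_rng(seed)
    resamples = rng.choice(d, size=(n_boot, n), replace=True)
    resamples.sort(axis=1)
    if est == "ba":
        means = resamples.mean(axis=1)
        sds = resamples.std(axis=1, ddof=1)
        lowers = means - BA_MULTIPLIER * sds
        uppers = means + BA_MULTIPLIER * sds
    else:
        w_lo = quantile_weights(est, n, 0.025)
        w_hi = quantile_weights(est, n, 0.975)
        lowers = resamples @ w_lo
        uppers = resamples @ w_hi
    alpha = (1.0 - level) / 2.0
    lo_ci = np.quantile(lowers, [alpha, 1.0 - alpha])
    hi_ci = np.quantile(uppers, [alpha, 1.0 - alpha])
    return BootstrapCI(
        ci_lower=(float(lo_ci[0]), float(lo_ci[1])),
        ci_upper=(float(hi_ci[0]), float(hi_ci[1])),
        estimator_id=est,
        n_boot=int(n_boot),
        level=float(level),
        seed=seed,
        n_rejected=0,
    )


def read_paired_data(
    path,
    columns: tuple[str | int, str | int] | None = None,
    sep: str | None = None,
    header: bool | None = None,
) -> PairedData:
    """Read paired measurements from a delimited text file.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with at least two numeric columns.
    columns : pair of names or 0-based indices, optional
        Which columns hold the two methods; defaults to the first two.
    sep : str, optional
        Field separator; sniffed by pandas when omitted.
    header : bool, optional
        Whether the first row is a header; auto-detected when omitted
        (non-numeric first row => header).
    """
    if header is None:
        probe = pd.read_csv(path, sep=sep, engine="python", header=None, nrows=1)
        first = probe.iloc[0]
        header = not all(
            isinstance(v, (int, float, np.number)) and np.isfinite(float(v))
            for v in pd.to_numeric(first, errors="coerce")
        )
    df = pd.read_csv(path, sep=sep, engine="python", header=0 if header else None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns, found {df.shape[1]}")
    if columns is None:
        c1, c2 = df.columns[0], df.columns[1]
    else:
        c1, c2 = (
            df.columns[c] if isinstance(c, int) else c for c in columns
        )
    m1 = pd.to_numeric(df[c1], errors="coerce").to_numpy()
    m2 = pd.to_numeric(df[c2], errors="coerce").to_numpy()
    return PairedData.from_arrays(m1, m2)
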