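"""Unit and property tests for the six L-statistic quantile estimators."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from nploa import (
    ESTIMATOR_IDS,
    LoAPair,
    OrderedSample,
    SampleTooSmallError,
    bp_quantile,
    estimate_loa,
    hd_quantile,
    hdlc_quantile,
    lc_weights,
    min_sample_size,
    no_quantile,
    quantile_weights,
    sq_quantile,
    sv_quantile,
)

QUANTILE_FUNCS = {
    "sq": sq_quantile,
    "hd": hd_quantile,
    "bp": bp_quantile,
    "hdlc": hdlc_quantile,
    "sv": sv_quantile,
    "no": no_quantile,
}


# ---------------------------------------------------------------------------
# exact hand-computed examples


@pytest.mark.parametrize(
    ("est", "values", "p", "expected"),
    [
        ("sq", [10, 20, 30], 0.5, 20.0),  # r=2, alpha=0: middle order statistic
        ("sq", np.arange(1, 101), 0.975, 98.475),  # r=98, alpha=0.475
        ("sq", np.arange(1, 101), 0.025, 2.525),  # r=2, alpha=0.525
        ("hd", [1, 3], 0.5, 2.0),  # Beta(1.5,1.5) symmetric about 1/2
        ("hd", [1, 2, 3, 4], 0.5, 2.5),  # weight symmetry W_i = W_{n+1-i}
        ("bp", [1, 3], 0.5, 2.0),
        ("bp", [1, 2, 3], 0.5, 2.0),  # weights (1/4, 1/2, 1/4)
        ("hdlc", [-2, -1, 1, 2], 0.5, 0.0),  # symmetric sample, symmetric Beta
        ("sv", [1, 2, 3, 4, 5], 0.5, 3.0),  # weight symmetry at p=1/2
        ("no", [1, 2, 3, 4, 5], 0.5, 3.0),
    ],
)
def test_exact_examples(est, values, p, expected):
    assert QUANTILE_FUNCS[est](values, p) == pytest.approx(expected, abs=1e-9)


def test_bp_weights_n3_are_quarter_half_quarter():
    np.testing.assert_allclose(
        quantile_weights("bp", 3, 0.5), [0.25, 0.5, 0.25], atol=1e-14
    )


def test_estimate_loa_sq_on_1_to_100():
    pair = estimate_loa(np.arange(1, 101), "sq")
    assert pair.lower == pytest.approx(2.525)
    assert pair.upper == pytest.approx(98.475)
    assert pair.estimator_id == "sq"
    assert pair.bias is None


def test_estimate_loa_constant_sample_degenerates_to_point():
    pair = estimate_loa(np.zeros(50), "sq")
    assert pair.lower == 0.0 and pair.upper == 0.0


# ---------------------------------------------------------------------------
# sample-size preconditions


@pytest.mark.parametrize("n", [5, 20, 30, 38])
def test_sq_undefined_below_minimum_at_loa_levels(n):
    with pytest.raises(SampleTooSmallError):
        sq_quantile(np.arange(n), 0.025)
    with pytest.raises(SampleTooSmallError):
        estimate_loa(np.arange(n), "sq")


def test_sq_defined_from_n_39_at_loa_levels():
    assert min_sample_size("sq") == 39
    pair = estimate_loa(np.arange(39), "sq")
    assert pair.lower <= pair.upper


@pytest.mark.parametrize("est", ["sv", "no"])
def test_sv_no_require_five_observations(est):
    with pytest.raises(SampleTooSmallError):
        QUANTILE_FUNCS[est]([1, 2, 3, 4], 0.5)
    QUANTILE_FUNCS[est]([1, 2, 3, 4, 5], 0.5)  # n=5 is fine


def test_lc_weights_invalid_n():
    with pytest.raises(ValueError):
        lc_weights(1)


def test_unknown_estimator_rejected():
    with pytest.raises(ValueError, match="unknown estimator"):
        quantile_weights("xyz", 10, 0.5)


# ---------------------------------------------------------------------------
# level-crossing weights


def test_lc_weights_n4_hand_values():
    w, q = lc_weights(4)
    s12 = math.sqrt(12.0)
    np.testing.assert_allclose(w[0], 0.5 * (1 - 2 / s12), rtol=1e-12)
    np.testing.assert_allclose(w[1], 1 / s12, rtol=1e-12)
    np.testing.assert_allclose(w, w[::-1], rtol=1e-12)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert q[-1] == 1.0


@given(st.integers(min_value=2, max_value=500))
def test_lc_weights_properties(n):
    w, q = lc_weights(n)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert w[0] == w[-1]
    assert np.all(np.diff(q) > 0)
    assert q[-1] == 1.0
    if n > 3:
        assert np.ptp(w[1:-1]) == 0.0  # all interior masses equal


# ---------------------------------------------------------------------------
# invariants across the (n, p) grid

GRID_N = (5, 10, 40, 50, 100, 1000)
GRID_P = (0.01, 0.025, 0.5, 0.975, 0.99)


@pytest.mark.parametrize("est", ESTIMATOR_IDS)
def test_weights_normalize_and_are_finite(est):
    """Every estimator's implied weights sum to 1 and contain no NaN/Inf."""
    for n in GRID_N:
        for p in GRID_P:
            try:
                w = quantile_weights(est, n, p)
            except SampleTooSmallError:
                assert est == "sq" or (est in ("sv", "no") and n < 5)
                continue
            assert np.all(np.isfinite(w)), (est, n, p)
            assert abs(w.sum() - 1.0) < 1e-10, (est, n, p)


@pytest.mark.parametrize("est", ESTIMATOR_IDS)
def test_tail_symmetry_of_weights(est):
    """Reversing the sample and the level p -> 1-p reverses the weights.

    All six estimators treat the lower and upper tail symmetrically; this is
    what makes their limits-of-agreement behavior mirror-imaged under
    symmetric distributions.
    """
    for n in (39, 50):
        for p in (0.025, 0.1):
            w_lo = quantile_weights(est, n, p)
            w_hi = quantile_weights(est, n, 1.0 - p)
            np.testing.assert_allclose(w_lo, w_hi[::-1], atol=1e-12)


@given(
    a=st.floats(min_value=0.01, max_value=100.0),
    b=st.floats(min_value=-50.0, max_value=50.0),
    p=st.sampled_from([0.025, 0.25, 0.5, 0.975]),
)
def test_location_scale_equivariance(a, b, p):
    x = np.sort(np.random.default_rng(42).standard_normal(50))
    for est in ESTIMATOR_IDS:
        q_x = QUANTILE_FUNCS[est](x, p)
        q_ax = QUANTILE_FUNCS[est](a * x + b, p)
        assert q_ax == pytest.approx(a * q_x + b, rel=1e-9, abs=1e-9)


@pytest.mark.parametrize("est", ESTIMATOR_IDS)
def test_median_of_symmetric_sample(est, rng):
    """At p=0.5 every estimator recovers the center of a symmetric sample."""
    half = rng.exponential(size=25)
    x = np.concatenate([3.0 - half, [3.0], 3.0 + half])
    assert QUANTILE_FUNCS[est](x, 0.5) == pytest.approx(3.0, abs=1e-9)


@pytest.mark.parametrize("est", ESTIMATOR_IDS)
def test_consistency_error_shrinks_with_n(est, rng):
    """Mean absolute error at p=0.975 decreases over n = 50, 200, 1000."""
    true_q = 0.975  # Uniform(0,1)
    maes = []
    for n in (50, 200, 1000):
        w = quantile_weights(est, n, 0.975)
        samples = rng.random((500, n))
        samples.sort(axis=1)
        maes.append(np.mean(np.abs(samples @ w - true_q)))
    assert maes[0] > maes[1] > maes[2]


# ---------------------------------------------------------------------------
# independent oracles


def _beta_quadrature_weights(n, p, edges):
    """Integrate the Beta(p(n+1), (1-p)(n+1)) density over each interval."""
    a, b = p * (n + 1), (1 - p) * (n + 1)
    pdf = stats.beta(a, b).pdf
    return np.array([
        integrate.quad(pdf, lo, hi, epsabs=1e-12, limit=200)[0]
        for lo, hi in zip(edges[:-1], edges[1:])
    ])


@pytest.mark.parametrize(("n", "p"), [(50, 0.975), (50, 0.025), (20, 0.5)])
def test_hd_weights_match_quadrature_oracle(n, p):
    edges = np.arange(n + 1) / n
    expected = _beta_quadrature_weights(n, p, edges)
    np.testing.assert_allclose(quantile_weights("hd", n, p), expected, atol=1e-8)


@pytest.mark.parametrize(("n", "p"), [(20, 0.975), (20, 0.025)])
def test_hdlc_weights_match_quadrature_oracle(n, p):
    edges = np.concatenate(([0.0], lc_weights(n).q))
    expected = _beta_quadrature_weights(n, p, edges)
    np.testing.assert_allclose(quantile_weights("hdlc", n, p), expected, atol=1e-8)


def test_hd_quantile_equals_oracle_dot_product():
    x = np.arange(1.0, 51.0)
    expected = _beta_quadrature_weights(50, 0.025, np.arange(51) / 50) @ x
    assert hd_quantile(x, 0.025) == pytest.approx(expected, abs=1e-8)


def _exact_binom_pmf(i, n, p: Fraction) -> Fraction:
    return Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i)


def _sv_oracle(x, n, p: Fraction):
    """Term-by-term transcription of the SV1 formula with exact rationals."""
    B = [_exact_binom_pmf(i, n, p) for i in range(n + 1)]
    X = lambda i: Fraction(int(x[i - 1]))  # 1-based order statistics
    total = (2 * B[0] + B[1]) / 2 * X(1) + B[0] / 2 * X(2) - B[0] / 2 * X(3)
    for i in range(2, n):
        total += (B[i] + B[i - 1]) / 2 * X(i)
    total += -B[n] / 2 * X(n - 2) + B[n] / 2 * X(n - 1) + (2 * B[n] + B[n - 1]) / 2 * X(n)
    return float(total)


def _no_oracle(x, n, p: Fraction):
    """Term-by-term transcription of the NO formula with exact rationals."""
    B = [_exact_binom_pmf(i, n, p) for i in range(n + 1)]
    X = lambda i: Fraction(int(x[i - 1]))
    total = (
        (B[0] * 2 * p + B[1] * p) * X(1)
        + B[0] * (2 - 3 * p) * X(2)
        - B[0] * (1 - p) * X(3)
    )
    for i in range(1, n - 1):
        total += (B[i] * (1 - p) + B[i + 1] * p) * X(i + 1)
    total += (
        -B[n] * p * X(n - 2)
        + B[n] * (3 * p - 1) * X(n - 1)
        + (B[n - 1] * (1 - p) + B[n] * (2 - 2 * p)) * X(n)
    )
    return float(total)


@pytest.mark.parametrize("p", [Fraction(1, 40), Fraction(39, 40), Fraction(1, 2)])
def test_sv_matches_exact_rational_transcription(p):
    x = np.arange(1, 11)
    assert sv_quantile(x, float(p)) == pytest.approx(_sv_oracle(x, 10, p), rel=1e-12)


@pytest.mark.parametrize("p", [Fraction(1, 40), Fraction(39, 40), Fraction(1, 2)])
def test_no_matches_exact_rational_transcription(p):
    x = np.arange(1, 11)
    assert no_quantile(x, float(p)) == pytest.approx(_no_oracle(x, 10, p), rel=1e-12)


# ---------------------------------------------------------------------------
# construction and misc


def test_ordered_sample_sorts_input():
    s = OrderedSample([3.0, 1.0, 2.0])
    np.testing.assert_array_equal(s.values, [1.0, 2.0, 3.0])
    assert s.n == len(s) == 3


def test_ordered_sample_rejects_bad_input():
    with pytest.raises(ValueError):
        OrderedSample([])
    with pytest.raises(ValueError):
        OrderedSample([1.0, np.nan])


@pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
def test_invalid_quantile_level_rejected(p):
    with pytest.raises(ValueError):
        hd_quantile([1.0, 2.0], p)


def test_loa_pair_is_plain_record():
    pair = LoAPair(lower=-1.0, upper=1.0, estimator_id="hd")
    assert (pair.lower, pair.upper) == (-1.0, 1.0)
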