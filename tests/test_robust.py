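"""Unit and property tests for the robust estimators.

Each estimator is checked against a brute-force oracle (tests/oracles.py)
on small random inputs, against hand-derived fixed cases, and for the
equivariance/symmetry properties that hold by construction.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampcnv.robust import (DegenerateInputError, benjamini_hochberg,
                           hodges_lehmann, mad, ned, sn_correlation,
                           sn_correlation_matrix, sn_scale,
                           studentized_residuals, theil_sen)

import oracles


def _random_vectors(seed, n_instances, n_min=2, n_max=8):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(n_min, n_max + 1))
        yield rng.normal(0.0, 10.0, size=n)


# ---------------------------------------------------------------------------
# oracle equivalence on small inputs
# ---------------------------------------------------------------------------

def test_sn_matches_bruteforce_oracle():
    for x in _random_vectors(1, 300):
        assert sn_scale(x) == pytest.approx(oracles.sn_oracle(list(x)), rel=1e-12)


def test_mad_matches_oracle():
    for x in _random_vectors(2, 300, n_min=1):
        assert mad(x) == pytest.approx(oracles.mad_oracle(list(x)), rel=1e-12)


def test_sn_correlation_matches_oracle():
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = int(rng.integers(3, 9))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        if mad(x) == 0 or mad(y) == 0:
            continue
        assert sn_correlation(x, y) == pytest.approx(
            oracles.sn_correlation_oracle(list(x), list(y)), rel=1e-10, abs=1e-10)


def test_theil_sen_matches_oracle():
    rng = np.random.default_rng(4)
    for _ in range(300):
        n = int(rng.integers(3, 9))
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        slope, intercept = oracles.theil_sen_oracle(list(x), list(y))
        model = theil_sen(x, y)
        assert model.slope == pytest.approx(slope, rel=1e-12, abs=1e-12)
        assert model.intercept == pytest.approx(intercept, rel=1e-12, abs=1e-12)


def test_hodges_lehmann_matches_oracle():
    for x in _random_vectors(5, 300, n_min=1):
        assert hodges_lehmann(x) == pytest.approx(
            oracles.hodges_lehmann_oracle(list(x)), rel=1e-12)


def test_ned_matches_oracle():
    rng = np.random.default_rng(6)
    for _ in range(200):
        n = int(rng.integers(1, 9))
        x, y = rng.normal(size=n), rng.normal(size=n)
        s = rng.uniform(0.1, 3.0, size=n)
        assert ned(x, y, s) == pytest.approx(
            oracles.ned_oracle(list(x), list(y), list(s)), rel=1e-12)


def test_benjamini_hochberg_matches_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        p = rng.uniform(size=int(rng.integers(1, 9)))
        np.testing.assert_allclose(benjamini_hochberg(p),
                                   oracles.benjamini_hochberg_oracle(list(p)),
                                   rtol=1e-12)


# ---------------------------------------------------------------------------
# fixed hand-derived cases
# ---------------------------------------------------------------------------

def test_sn_fixed_cases():
    assert sn_scale([5, 5, 5, 5]) == 0.0
    # (1..5): inner high medians (3,2,2,2,3), low median 2, times 1.1926*1.351
    assert sn_scale([1, 2, 3, 4, 5]) == pytest.approx(1.1926 * 1.351 * 2)
    with pytest.raises(ValueError):
        sn_scale([1.0])


def test_mad_fixed_cases():
    assert mad([1, 1, 1]) == 0.0
    assert mad([1, 2, 3, 4, 100]) == pytest.approx(1.4826)
    with pytest.raises(ValueError):
        mad([])


def test_theil_sen_fixed_cases():
    m = theil_sen([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
    assert m.slope == pytest.approx(1.0)
    assert m.intercept == pytest.approx(0.0)
    assert m.residual_scale == 0.0
    # one wild outlier leaves the fit untouched
    m = theil_sen(np.arange(5.0), np.array([0.0, 2.0, 4.0, 6.0, 100.0]))
    assert m.slope == pytest.approx(2.0)
    assert m.intercept == pytest.approx(0.0)
    with pytest.raises(DegenerateInputError):
        theil_sen([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def test_hodges_lehmann_fixed_cases():
    assert hodges_lehmann([1, 2, 3]) == pytest.approx(2.0)
    # Walsh multiset of (0,0,0,10) is six 0s, three 5s, one 10 -> median 0
    assert hodges_lehmann([0, 0, 0, 10]) == pytest.approx(0.0)


def test_ned_fixed_cases():
    assert ned([1.0, 2.0], [1.0, 2.0], [1.0, 1.0]) == 0.0
    assert ned([1.0, 2.0], [0.0, 0.0], [1.0, 2.0]) == pytest.approx(np.sqrt(2))
    with pytest.raises(ValueError):
        ned([1.0], [0.0], [0.0])


def test_benjamini_hochberg_fixed_cases():
    np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


def test_sn_correlation_perfect_and_anti():
    x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
    assert sn_correlation(x, x) == pytest.approx(1.0)
    assert sn_correlation(x, -x) == pytest.approx(-1.0)
    with pytest.raises(DegenerateInputError):
        sn_correlation(x, np.ones_like(x))


# ---------------------------------------------------------------------------
# studentized residuals
# ---------------------------------------------------------------------------

def test_studentized_residuals_flag_planted_outlier():
    rng = np.random.default_rng(11)
    x = np.linspace(0.0, 9.0, 10)
    y = 2.0 * x + 1.0 + rng.normal(0.0, 0.1, size=10)
    model = theil_sen(x, y)
    y2 = y.copy()
    y2[5] += 10.0 * model.residual_scale
    model2 = theil_sen(x, y2)
    r = studentized_residuals(model2, x, y2)
    assert np.argmax(np.abs(r)) == 5
    assert abs(r[5]) > 3.0


def test_studentized_residuals_match_direct_formula():
    rng = np.random.default_rng(12)
    x = rng.normal(size=5)
    y = 1.5 * x + rng.normal(size=5)
    model = theil_sen(x, y)
    expected = oracles.studentized_oracle(model.slope, model.intercept,
                                          model.residual_scale, list(x), list(y))
    np.testing.assert_allclose(studentized_residuals(model, x, y), expected,
                               rtol=1e-12)


def test_studentized_residuals_reject_perfect_fit():
    x = np.arange(5.0)
    model = theil_sen(x, 2 * x)
    with pytest.raises(DegenerateInputError):
        studentized_residuals(model, x, 2 * x)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(finite_floats, min_size=2, max_size=20),
       st.floats(0.1, 100.0), st.floats(-100.0, 100.0))
def test_sn_and_mad_equivariance(xs, a, b):
    x = np.asarray(xs)
    assert sn_scale(a * x + b) == pytest.approx(a * sn_scale(x),
                                                rel=1e-9, abs=1e-6)
    assert mad(a * x + b) == pytest.approx(a * mad(x), rel=1e-9, abs=1e-6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 1000))
def test_sn_correlation_symmetry_and_bounds(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    x = rng.normal(size=n)
    y = rng.normal(size=n) + 0.3 * x
    r = sn_correlation(x, y)
    assert -1.0 <= r <= 1.0
    assert r == pytest.approx(sn_correlation(y, x), rel=1e-12, abs=1e-12)
    # invariance under positive affine transforms of one argument
    assert r == pytest.approx(sn_correlation(3.0 * x + 7.0, y),
                              rel=1e-9, abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 1000))
def test_theil_sen_equivariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = 2.0 * x + rng.normal(size=12)
    base = theil_sen(x, y)
    shifted = theil_sen(x + 5.0, y - 3.0)
    assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
    scaled = theil_sen(x, 4.0 * y)
    assert scaled.slope == pytest.approx(4.0 * base.slope, rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30))
def test_bh_adjusted_never_below_raw(ps):
    adj = benjamini_hochberg(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all(adj <= 1.0)


def test_hodges_lehmann_equals_median_for_symmetric_data():
    x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
    assert hodges_lehmann(x) == pytest.approx(np.median(x))


def test_mad_affine_equivariance_random():
    rng = np.random.default_rng(21)
    x = rng.normal(size=50)
    assert mad(2 * x + 7) == pytest.approx(2 * mad(x))


# ---------------------------------------------------------------------------
# statistical consistency
# ---------------------------------------------------------------------------

def test_sn_consistent_for_normal_scale():
    rng = np.random.default_rng(31)
    x = rng.normal(size=10_000)
    assert sn_scale(x) == pytest.approx(1.0, rel=0.02)


def test_sn_correlation_tracks_pearson_on_clean_gaussian():
    rng = np.random.default_rng(32)
    z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=1000)
    pearson = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
    assert sn_correlation(z[:, 0], z[:, 1]) == pytest.approx(pearson, abs=0.1)


def test_theil_sen_resists_25pct_contamination():
    rng = np.random.default_rng(33)
    x = rng.uniform(0.0, 10.0, size=20)
    y = 3.0 * x + 1.0 + rng.normal(0.0, 0.1, size=20)
    idx = rng.choice(20, size=5, replace=False)
    y[idx] = rng.uniform(50.0, 100.0, size=5)
    assert theil_sen(x, y).slope == pytest.approx(3.0, abs=0.1)


def test_log_poisson_variance_scales_inversely_with_rate():
    # basis of the supervised variance corrections (factors 2 and 2/3)
    rng = np.random.default_rng(34)
    for lam in (500.0, 1000.0):
        v = np.var(np.log(rng.poisson(lam, size=20_000)))
        assert v == pytest.approx(1.0 / lam, rel=0.1)


def test_sn_correlation_matrix_consistent_with_pairwise():
    rng = np.random.default_rng(35)
    rows = rng.normal(size=(6, 40))
    rows[1] = rows[0] * 2.0 + rng.normal(0, 0.1, size=40)
    mat = sn_correlation_matrix(rows)
    for i in range(6):
        for j in range(i + 1, 6):
            assert mat[i, j] == pytest.approx(
                sn_correlation(rows[i], rows[j]), rel=1e-9, abs=1e-9)
    assert np.allclose(np.diag(mat), 1.0)
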