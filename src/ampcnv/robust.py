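"""Robust estimators used throughout the caller.

Amplicon coverages carry outliers by construction: the anomalies (copy-number
variants) are exactly the points that must not distort the fitted baseline.
Every estimator here therefore has a high breakdown point:

* ``sn_scale`` — Rousseeuw–Croux Sn scale (nested medians of pairwise
  absolute differences), the robust stand-in for the standard deviation.
* ``mad`` — median absolute deviation with the normal-consistency constant.
* ``sn_correlation`` — Gnanadesikan–Kettenring-style robust correlation built
  from Sn scales of the sum and difference of MAD-standardised variables.
* ``theil_sen`` — median-of-pairwise-slopes regression (breakdown point
  1 − 1/sqrt(2) ≈ 29.3 %).
* ``studentized_residuals`` — internally studentized residuals with Sn
  replacing the residual standard deviation.
* ``hodges_lehmann`` — median of Walsh averages (robust location).
* ``ned`` — normalised Euclidean distance (per-coordinate scaling).
* ``benjamini_hochberg`` — step-up FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateInputError",
    "RobustLinearModel",
    "sn_scale",
    "mad",
    "sn_correlation",
    "sn_correlation_matrix",
    "theil_sen",
    "studentized_residuals",
    "hodges_lehmann",
    "ned",
    "benjamini_hochberg",
]


class DegenerateInputError(ValueError):
    """Input has no usable dispersion (e.g. MAD = 0, perfect fit)."""


# ---------------------------------------------------------------------------
# Sn scale
# ---------------------------------------------------------------------------

_SN_CONSISTENCY = 1.1926
# Rousseeuw–Croux finite-sample correction factors for n = 2..9; beyond that
# n/(n - 0.9) for odd n and 1.0 for even n.
_SN_SMALL_N = {2: 0.743, 3: 1.851, 4: 0.954, 5: 1.351,
               6: 0.993, 7: 1.198, 8: 1.005, 9: 1.131}


def _sn_finite_correction(n: int) -> float:
    if n <= 9:
        return _SN_SMALL_N[n]
    return n / (n - 0.9) if n % 2 else 1.0


def _sn_batch(rows: np.ndarray) -> np.ndarray:
    """Sn of each row of a (B, n) array.

    Inner statistic: high median over j != i of |x_i - x_j| (index
    floor((n-1)/2) + 1, 1-based, among the n - 1 differences); outer: low
    median over i. O(B n^2) time; chunked so memory stays bounded.
    """
    b, n = rows.shape
    k_in = (n - 1) // 2
    k_out = (n + 1) // 2 - 1
    inner = np.empty((b, n))
    # keep each |x_i - x_j| block under ~2e7 elements
    step = max(1, int(2e7 // (n * n)))
    if b == 1:
        x = rows[0]
        row_step = max(1, int(2e7 // n))
        for lo in range(0, n, row_step):
            hi = min(lo + row_step, n)
            diff = np.abs(x[lo:hi, None] - x[None, :])
            diff[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
            inner[0, lo:hi] = np.partition(diff, k_in, axis=1)[:, k_in]
    else:
        idx = np.arange(n)
        for lo in range(0, b, step):
            hi = min(lo + step, b)
            diff = np.abs(rows[lo:hi, :, None] - rows[lo:hi, None, :])
            diff[:, idx, idx] = np.inf  # exclude j == i
            inner[lo:hi] = np.partition(diff, k_in, axis=2)[:, :, k_in]
    outer = np.partition(inner, k_out, axis=1)[:, k_out]
    return _SN_CONSISTENCY * _sn_finite_correction(n) * outer


def sn_scale(values) -> float:
    """Rousseeuw–Croux Sn scale estimate of a 1-D sample (n >= 2).

    Returns 0 iff all values are equal; scale-equivariant and
    translation-invariant.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("sn_scale expects a 1-D array")
    if x.size < 2:
        raise ValueError(f"sn_scale needs n >= 2, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sn_scale requires finite values")
    return float(_sn_batch(x[None, :])[0])


# ---------------------------------------------------------------------------
# MAD and robust correlation
# ---------------------------------------------------------------------------

def mad(values, constant: float = 1.4826) -> float:
    """Median absolute deviation about the median, scaled for normal
    consistency (constant 1.4826)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of empty input")
    return float(constant * np.median(np.abs(x - np.median(x))))


def _principal_variables(x: np.ndarray, y: np.ndarray):
    """Robust principal variables u = zx + zy, v = zx - zy with
    z = (x - med(x)) / (sqrt(2) * MAD(x))."""
    mx, my = mad(x), mad(y)
    if mx == 0.0 or my == 0.0:
        raise DegenerateInputError("MAD of an argument is zero")
    zx = (x - np.median(x)) / (np.sqrt(2.0) * mx)
    zy = (y - np.median(y)) / (np.sqrt(2.0) * my)
    return zx + zy, zx - zy


def sn_correlation(x, y) -> float:
    """Robust correlation (Sn^2(u) - Sn^2(v)) / (Sn^2(u) + Sn^2(v)).

    u, v are the sum/difference of the MAD-standardised variables; the result
    is symmetric, bounded in [-1, 1] and invariant under positive affine
    transforms of either argument.  Consistent for the Pearson coefficient at
    the bivariate normal model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sn_correlation expects two equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("sn_correlation needs n >= 3")
    u, v = _principal_variables(x, y)
    su2 = sn_scale(u) ** 2
    sv2 = sn_scale(v) ** 2
    tot = su2 + sv2
    if tot == 0.0:
        raise DegenerateInputError("both principal variables are constant")
    return float(np.clip((su2 - sv2) / tot, -1.0, 1.0))


def sn_correlation_matrix(rows: np.ndarray, chunk: int = 2000) -> np.ndarray:
    """Pairwise Sn-correlation matrix for the rows of a (m, n) array.

    Rows with MAD = 0 are degenerate; their entries are NaN.  The diagonal is
    1 for non-degenerate rows.  Work is chunked over row pairs to bound
    memory (each pair costs O(n^2)).
    """
    rows = np.asarray(rows, dtype=float)
    m, n = rows.shape
    meds = np.median(rows, axis=1)
    mads = np.array([mad(r) for r in rows])
    ok = mads > 0.0
    corr = np.full((m, m), np.nan)
    corr[np.ix_(ok, ok)] = 0.0
    corr[ok, ok] = 1.0
    z = np.zeros_like(rows)
    z[ok] = (rows[ok] - meds[ok, None]) / (np.sqrt(2.0) * mads[ok, None])
    iu, ju = np.triu_indices(m, k=1)
    keep = ok[iu] & ok[ju]
    iu, ju = iu[keep], ju[keep]
    for lo in range(0, iu.size, chunk):
        ii = iu[lo:lo + chunk]
        jj = ju[lo:lo + chunk]
        su2 = _sn_batch(z[ii] + z[jj]) ** 2
        sv2 = _sn_batch(z[ii] - z[jj]) ** 2
        tot = su2 + sv2
        with np.errstate(invalid="ignore"):
            r = np.clip((su2 - sv2) / tot, -1.0, 1.0)
        r[tot == 0.0] = np.nan
        corr[ii, jj] = r
        corr[jj, ii] = r
    return corr


# ---------------------------------------------------------------------------
# Theil-Sen regression and studentized residuals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustLinearModel:
    """Theil-Sen line with an Sn residual scale.

    ``predictor_mean`` and ``predictor_ss`` (sum of squared deviations of x)
    feed the leverage terms of the studentized residuals.
    """

    slope: float
    intercept: float
    residual_scale: float
    n: int
    predictor_mean: float
    predictor_ss: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def residuals(self, x, y) -> np.ndarray:
        return np.asarray(y, dtype=float) - self.predict(x)


def theil_sen(x, y) -> RobustLinearModel:
    """Theil-Sen fit: slope = median of pairwise slopes (pairs with equal x
    skipped), intercept = median(y - slope * x), residual scale = Sn of the
    residuals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("theil_sen expects two equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("theil_sen needs n >= 3")
    if np.all(x == x[0]):
        raise DegenerateInputError("all predictor values identical")
    slope, intercept, _, _ = _stats.theilslopes(y, x, method="joint")
    resid = y - slope * x - intercept
    xbar = float(np.mean(x))
    return RobustLinearModel(
        slope=float(slope),
        intercept=float(intercept),
        residual_scale=sn_scale(resid),
        n=n,
        predictor_mean=xbar,
        predictor_ss=float(np.sum((x - xbar) ** 2)),
    )


def studentized_residuals(model: RobustLinearModel, x, y) -> np.ndarray:
    """Internally studentized residuals with Sn as the scale:
    r_i = e_i / (Sn * sqrt(1 - h_i)), h_i = 1/n + (x_i - xbar)^2 / SS_x."""
    if model.residual_scale <= 0.0:
        raise DegenerateInputError(
            "residual scale is zero (perfect fit); residuals cannot be studentized")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = model.residuals(x, y)
    h = 1.0 / model.n + (x - model.predictor_mean) ** 2 / model.predictor_ss
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    return resid / (model.residual_scale * np.sqrt(1.0 - h))


# ---------------------------------------------------------------------------
# Location, distance, FDR
# ---------------------------------------------------------------------------

def hodges_lehmann(values) -> float:
    """Hodges–Lehmann location: median of all Walsh averages
    (x_i + x_j)/2 over pairs i <= j (singletons included)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("hodges_lehmann of empty input")
    i, j = np.triu_indices(x.size)
    return float(np.median((x[i] + x[j]) / 2.0))


def ned(x, y, s) -> float:
    """Normalised Euclidean distance sqrt(sum((x_i - y_i)^2 / s_i^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (x.shape == y.shape == s.shape) or x.ndim != 1:
        raise ValueError("ned expects three equal-length 1-D arrays")
    if np.any(s <= 0.0):
        raise ValueError("ned scales must be strictly positive")
    return float(np.sqrt(np.sum((x - y) ** 2 / s ** 2)))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0.0) | (p > 1.0)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
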