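"""Statistical kernels used by every pipeline stage.

All kernels are pure and deterministic. P-values are never reported as
exactly zero: they are floored at the smallest positive normal double and
the result carries ``p_floored=True`` when the floor was applied.

Conventions
-----------
* Standard deviations use the sample convention (``ddof=1``) throughout.
* All tests are two-sided.
* Degenerate inputs (zero variance, empty effective sample) return flagged
  results instead of raising, so that genome-scale screens can continue.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import CollinearityError, PValueError, ValidationError

logger = logging.getLogger(__name__)

_P_FLOOR = np.finfo(float).tiny


def _floor_p(p: float) -> tuple[float, bool]:
    if p <= 0.0:
        return _P_FLOOR, True
    return float(min(p, 1.0)), False


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df_or_n`` holds degrees of freedom where the reference distribution
    has them, otherwise the effective sample size. ``extra`` carries
    method-specific summaries (e.g. the median difference for the
    signed-rank test).
    """

    statistic: float
    p_value: float
    method: str
    df_or_n: float
    degenerate: bool = False
    p_floored: bool = False
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 table of counts; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError(f"cell counts must be non-negative integers: {cells}")
        if sum(cells) < 1:
            raise ValidationError("grand total must be at least 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def validate_pvalues(p) -> np.ndarray:
    """Return ``p`` as a 1-D float array, rejecting anything outside [0, 1]."""
    arr = np.asarray(p, dtype=float).ravel()
    if arr.size == 0:
        raise PValueError("empty p-value vector")
    if not np.all(np.isfinite(arr)):
        raise PValueError("p-values must be finite")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise PValueError("p-values must lie in [0, 1]")
    return arr


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, aligned with the input order.

    q_(i) = min over j >= i of m * p_(j) / j (order statistics), clipped
    at 1. Output is component-wise >= p and monotone non-decreasing in p.
    """
    arr = validate_pvalues(p)
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    slope: float
    mean_y: float
    n: int
    degenerate: bool = False
    p_floored: bool = False


def pearson_age_corr(x, y) -> PearsonResult:
    """Pearson correlation of ``y`` on ``x`` with OLS slope and mean.

    The p-value uses the exact t transform ``t = r*sqrt((n-2)/(1-r^2))``
    against Student's t with n-2 degrees of freedom, two-sided. A constant
    ``y`` yields a degenerate (flagged) result; a constant ``x`` is a
    caller error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0.0:
        raise ValidationError("x is constant; correlation with age undefined")
    mean_y = float(y.mean())
    yc = y - mean_y
    ssy = float(yc @ yc)
    if ssy == 0.0:
        return PearsonResult(np.nan, np.nan, 0.0, mean_y, n, degenerate=True)
    sxy = float(xc @ yc)
    r = sxy / np.sqrt(ssx * ssy)
    r = float(np.clip(r, -1.0, 1.0))
    slope = sxy / ssx
    if abs(r) == 1.0:
        p, floored = _floor_p(0.0)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p, floored = _floor_p(2.0 * sps.t.sf(abs(t), n - 2))
    return PearsonResult(r, p, float(slope), mean_y, n, p_floored=floored)


def _signed_rank_exact_sf_cdf(ranks2: np.ndarray, w2: float) -> tuple[float, float]:
    """Exact P(W <= w) and P(W >= w) for the signed-rank sum.

    ``ranks2`` are midranks doubled to integers (handles ties exactly);
    ``w2`` the doubled observed positive-rank sum. Uses the standard
    generating-function convolution over 2^n equiprobable sign vectors.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()
    w2i = int(round(w2))
    cdf = counts[: w2i + 1].sum() / denom
    sf = counts[w2i:].sum() / denom
    return cdf, sf


def wilcoxon_one_sample(values, mu0: float = 0.0, mode: str = "auto") -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test of median == mu0.

    Values equal to ``mu0`` are dropped (classic convention). ``mode``:
    ``exact`` enumerates the signed-rank null (tie-exact, via doubled
    midranks); ``approx`` uses the normal approximation with tie
    correction; ``auto`` picks exact for effective n <= 25.
    """
    if mode not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown mode {mode!r}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("values must be a non-empty 1-D vector")
    d = v - mu0
    median_diff = float(np.median(d))
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon-one-sample", 0, degenerate=True,
                          extra={"median_diff": median_diff, "n_dropped": v.size})
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    use_exact = mode == "exact" or (mode == "auto" and n <= 25)
    if use_exact:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        w2 = 2.0 * w_pos
        cdf, sf = _signed_rank_exact_sf_cdf(ranks2, w2)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "wilcoxon-one-sample-exact"
    else:
        mean_w = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var_w <= 0:
            return TestResult(w_pos, 1.0, "wilcoxon-one-sample-approx", n,
                              degenerate=True, extra={"median_diff": median_diff})
        z = (w_pos - mean_w) / np.sqrt(var_w)
        p = 2.0 * sps.norm.sf(abs(z))
        method = "wilcoxon-one-sample-approx"
    p, floored = _floor_p(p)
    return TestResult(w_pos, p, method, n, p_floored=floored,
                      extra={"median_diff": median_diff})


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across groups (tie-corrected, chi2 reference)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", len(groups) - 1, degenerate=True)
    h, p = sps.kruskal(*groups)
    p, floored = _floor_p(p)
    return TestResult(float(h), p, "kruskal-wallis", len(groups) - 1,
                      p_floored=floored)


def chi_square_2x2(table: Contingency2x2, correction: str = "none") -> TestResult:
    """Chi-squared test of independence for a 2x2 table.

    With ``correction='none'``: chi2 = N*(ad-bc)^2 / (row and column
    margin product). Yates subtracts N/2 from |ad-bc|, floored at 0. The
    default is no correction. A warning is logged when any expected count
    falls below 5.
    """
    if correction not in ("none", "yates"):
        raise ValidationError(f"unknown correction {correction!r}")
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValidationError("a zero row or column margin makes chi2 undefined")
    expected_min = min((a + b) * (a + c), (a + b) * (b + d),
                       (c + d) * (a + c), (c + d) * (b + d)) / n
    if expected_min < 5:
        logger.warning("chi_square_2x2: smallest expected count %.2f < 5; "
                       "consider fisher_exact_2x2", expected_min)
    diff = abs(a * d - b * c)
    if correction == "yates":
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p, floored = _floor_p(sps.chi2.sf(chi2, 1))
    return TestResult(float(chi2), p, f"chi2-2x2-{correction}", 1, p_floored=floored)


def fisher_exact_2x2(table: Contingency2x2) -> TestResult:
    """Fisher's exact test, two-sided (sum of tables no more probable)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValidationError("a zero row or column margin makes the test undefined")
    odds, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    p, floored = _floor_p(p)
    return TestResult(float(odds), p, "fisher-exact-2x2", a + b + c + d,
                      p_floored=floored)


@dataclass(frozen=True)
class OLSResult:
    r2: float
    coefficients: np.ndarray
    coef_p: np.ndarray
    names: tuple[str, ...]
    n: int


def ols_fit(y, X, names=None, add_intercept: bool = True) -> OLSResult:
    """Ordinary least squares of ``y`` on the columns of ``X``.

    An intercept is prepended by default. Rank-deficient designs raise
    :class:`CollinearityError` naming the offending columns (those whose
    removal restores full rank).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if X.shape[0] != y.size:
        raise ValidationError("y and X have incompatible shapes")
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    names = list(names)
    if len(names) != k:
        raise ValidationError("names must match the number of design columns")
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
    k_full = X.shape[1]
    if n <= k_full - (1 if add_intercept else 0):
        raise ValidationError(f"need n > number of covariates; n={n}, k={k}")
    rank = np.linalg.matrix_rank(X)
    if rank < k_full:
        collinear = [
            names[j] for j in range(k_full)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise CollinearityError(collinear)
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    return OLSResult(
        r2=float(fit.rsquared),
        coefficients=np.asarray(fit.params, dtype=float),
        coef_p=np.asarray(fit.pvalues, dtype=float),
        names=tuple(names),
        n=n,
    )


def all_balanced_assignments(n_total: int, n_group1: int):
    """Iterate index tuples for group 1 over all balanced label assignments."""
    return itertools.combinations(range(n_total), n_group1)
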