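"""Independent brute-force / closed-form oracles for the statistical kernels.

Each oracle evaluates the textbook definition directly (enumeration or
explicit formula) and is kept free of any code path from the package.
"""

import itertools

import numpy as np
from scipy import stats as sps


def bh_stepup_bruteforce(p):
    """Direct O(m^2) evaluation of the BH step-up definition.

    q for the i-th order statistic is the minimum of m*p_(j)/j over all
    j >= i, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        best = 1.0
        for j in range(pos, m):
            best = min(best, m * p[order[j]] / (j + 1))
        q[idx] = best
    return q


def wilcoxon_exact_bruteforce(values, mu0=0.0):
    """Two-sided signed-rank p by exhaustive sign-assignment enumeration."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    # all 2^n sign assignments as a bit matrix
    bits = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    w_all = bits @ ranks
    eps = 1e-9
    cdf = np.mean(w_all <= w_obs + eps)
    sf = np.mean(w_all >= w_obs - eps)
    return min(1.0, 2.0 * min(cdf, sf))


def kruskal_bruteforce(groups):
    """H with tie correction from the explicit rank formula."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    h /= correction
    p = sps.chi2.sf(h, len(groups) - 1)
    return h, p


def chi2_2x2_closed_form(a, b, c, d, yates=False):
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return chi2, sps.chi2.sf(chi2, 1)


def fisher_2x2_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def ols_normal_equations(y, X):
    """OLS via explicit normal equations with coefficient t-tests."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    sigma2 = ss_res / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), n - k)
    return r2, beta, p


def pearson_closed_form(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    r = (((x - x.mean()) * (y - y.mean())).sum()
         / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, p


def all_sign_combinations(n):
    return itertools.product([-1, 1], repeat=n)
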