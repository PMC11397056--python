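"""Independent brute-force oracles, coded separately from the package paths.

These deliberately use plain loops and literal definitions so they share no
code with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betainc
from scipy.stats import nbinom


def bh_oracle(pvalues):
    """Literal Benjamini-Hochberg step-up definition."""
    p = list(map(float, pvalues))
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p[i] * m / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(indexed, start=1):
        out[i] = adj_sorted[rank - 1]
    return np.array(out)


def holm_oracle(pvalues):
    """Literal Holm step-down definition."""
    p = list(map(float, pvalues))
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 0.0
    for rank, i in enumerate(indexed, start=1):
        running = max(running, (m - rank + 1) * p[i])
        out[i] = min(running, 1.0)
    return np.array(out)


def pearson_oracle(x, y):
    """Definitional Pearson r and two-sided t p-value via the incomplete beta."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    if abs(r) >= 1.0:
        return r, float(np.finfo(float).eps)
    t2 = r * r * df / (1 - r * r)
    # two-sided p of |t|: regularized incomplete beta I_{df/(df+t^2)}(df/2, 1/2)
    p = betainc(df / 2.0, 0.5, df / (df + t2))
    return r, float(p)


def tmm_oracle(counts, sample_j, ref_j, trim_m=0.30, trim_a=0.05):
    """Brute-force single-sample TMM factor (unscaled), plain loops.

    Follows the trim-and-weight recipe: positive-in-both features, M and A
    values, rank-based double trimming, inverse-variance weighted mean M.
    """
    counts = np.asarray(counts, dtype=float)
    n_obs = counts[:, sample_j].sum()
    n_ref = counts[:, ref_j].sum()
    m_vals, a_vals, w_vals = [], [], []
    for g in range(counts.shape[0]):
        y_s, y_r = counts[g, sample_j], counts[g, ref_j]
        if y_s <= 0 or y_r <= 0:
            continue
        m = math.log2((y_s / n_obs) / (y_r / n_ref))
        a = 0.5 * math.log2((y_s / n_obs) * (y_r / n_ref))
        v = (n_obs - y_s) / (n_obs * y_s) + (n_ref - y_r) / (n_ref * y_r)
        m_vals.append(m)
        a_vals.append(a)
        w_vals.append(1.0 / v)
    n = len(m_vals)
    if n == 0:
        return float("nan")
    if max(abs(m) for m in m_vals) < 1e-6:
        return 1.0

    def ranks(vals):
        order = sorted(range(n), key=lambda i: vals[i])
        rk = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                rk[order[k]] = avg
            i = j + 1
        return rk

    rm, ra = ranks(m_vals), ranks(a_vals)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    for i in range(n):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += w_vals[i] * m_vals[i]
            den += w_vals[i]
    if den == 0:
        return float("nan")
    return 2.0 ** (num / den)


def exact_test_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Exhaustive conditional NB exact test via scipy's nbinom pmf.

    Group sums are NB with mean n*mu and dispersion phi/n; conditional on the
    total, the two-sided p sums probabilities of splits no more probable than
    the observed one.
    """
    total = int(sum_a + sum_b)
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)

    def pmf(x, mean, disp):
        r = 1.0 / disp
        return nbinom.pmf(x, r, r / (r + mean))

    probs = []
    for a in range(total + 1):
        probs.append(pmf(a, n_a * mu, phi / n_a) * pmf(total - a, n_b * mu, phi / n_b))
    z = sum(probs)
    obs = probs[int(sum_a)]
    p = sum(q for q in probs if q <= obs * (1 + 1e-12)) / z
    return min(1.0, p)


def nb_loglik(y, mu, phi):
    """NB log-likelihood for the LRT oracle."""
    r = 1.0 / phi
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    from scipy.special import gammaln
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))
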