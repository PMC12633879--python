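"""Shared statistical primitives.

Vectorised conditional-hypergeometric Fisher tests, Benjamini-Hochberg
adjustment and a moderated two-sample t-test used by the contrast engines.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

# Relative tolerance used when summing table probabilities <= observed,
# matching the convention of common Fisher implementations so that ties
# in the conditional pmf are counted despite floating-point rounding.
_PMF_TIE_GAMMA = 1e-7


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def fisher_exact_batch(a, b, c, d) -> np.ndarray:
    """Two-sided Fisher exact p-values for 2x2 tables [[a, b], [c, d]].

    The two-sided p is the sum of hypergeometric probabilities (conditional
    on the table margins) of all tables as or less probable than the one
    observed. All four arguments broadcast to a common shape; an all-zero
    table yields p = 1.
    """
    a, b, c, d = np.broadcast_arrays(
        *(np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    )
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("table entries must be non-negative")
    shape = a.shape
    a, b, c, d = (x.ravel() for x in (a, b, c, d))
    n_tab = a.size
    total = a + b + c + d
    col1 = a + c
    row1 = a + b

    lo = np.maximum(0, col1 + row1 - total)
    hi = np.minimum(col1, row1)
    lens = hi - lo + 1
    starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
    idx = np.repeat(np.arange(n_tab), lens)
    x = np.arange(lens.sum()) - starts[idx] + lo[idx]

    n_i, k_i, r_i = total[idx], col1[idx], row1[idx]
    log_pmf = (
        _log_choose(k_i, x)
        + _log_choose(n_i - k_i, r_i - x)
        - _log_choose(n_i, r_i)
    )
    log_obs = (
        _log_choose(col1, a)
        + _log_choose(total - col1, row1 - a)
        - _log_choose(total, row1)
    )
    keep = log_pmf <= log_obs[idx] + np.log1p(_PMF_TIE_GAMMA)
    p = np.bincount(idx, weights=np.exp(log_pmf) * keep, minlength=n_tab)
    return np.clip(p, 0.0, 1.0).reshape(shape)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a single 2x2 table."""
    return float(fisher_exact_batch(a, b, c, d))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")[::-1]
    scaled = p[order] * m / np.arange(m, 0, -1)
    adjusted = np.minimum.accumulate(scaled)
    out = np.empty(m, dtype=float)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def _trigamma_inverse(y: float, iterations: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(iterations):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = max(x - step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def fit_scaled_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled-F prior to per-feature residual variances.

    Matches the mean and spread of log(s2) against a scaled F(df, d0)
    distribution, the standard empirical-Bayes treatment of per-feature
    variances. Returns (prior_df d0, prior variance s2_0); d0 is infinite
    when the observed log-variances are no more spread than chi-square
    sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s2_0 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s2_0


def moderated_two_sample(
    x: np.ndarray, y: np.ndarray, prior_df: float | None = None
):
    """Row-wise two-sample t-test with empirical-Bayes variance moderation.

    ``x`` and ``y`` are (features x replicates) arrays on a log scale.
    Per-feature pooled variances are shrunk toward a prior variance whose
    weight (prior degrees of freedom) is estimated from the spread of the
    observed log-variances (``prior_df=None``), stabilising tests at two
    or three replicates; pass a number to fix the prior weight instead.
    Returns ``(delta, p)`` where ``delta`` is ``rowmean(x) - rowmean(y)``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    delta = x.mean(axis=1) - y.mean(axis=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / df
    if prior_df is None:
        d0, s2_0 = fit_scaled_f_prior(s2, df)
    else:
        d0, s2_0 = float(prior_df), float(np.mean(s2))
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s2_0)
        df_total = 1e6
    else:
        s2_mod = (d0 * s2_0 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return delta, np.clip(p, 0.0, 1.0)


def weighted_median(values, weights) -> float:
    """Weighted median: minimiser of sum(w * |v - m|)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    order = np.argsort(v)
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    cutoff = 0.5 * cum[-1]
    i = int(np.searchsorted(cum, cutoff))
    if np.isclose(cum[i], cutoff) and i + 1 < v.size:
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])
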