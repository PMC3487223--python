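"""Independent reference implementations used as test oracles.

Everything here is written with plain loops directly from the method
definitions (brute-force enumeration, direct arithmetic) and shares no code
with the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np


def direct_d(values, s0):
    """One-sample SAM d by direct arithmetic."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean / (sqrt(var) / sqrt(n) + s0)


def enumerate_sign_flip_d(matrix, s0):
    """All 2^n sign-flip permutations; each row the sorted d vector."""
    matrix = np.asarray(matrix, float)
    n = matrix.shape[1]
    rows = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        rows.append(sorted(direct_d(row * np.array(signs), s0) for row in matrix))
    return np.array(rows)


def brute_sam_q(matrix, s0):
    """SAM q-values by direct per-Delta loops (observed d, q vector, pi0)."""
    matrix = np.asarray(matrix, float)
    m, n = matrix.shape
    d = np.array([direct_d(row, s0) for row in matrix])
    perms = enumerate_sign_flip_d(matrix, s0)

    order = np.argsort(d, kind="stable")
    ds = d[order]
    dbar = perms.mean(axis=0)
    pooled = np.sort(perms.ravel())
    q25, q75 = np.percentile(pooled, [25, 75])
    pi0 = min(1.0, sum(1 for v in d if q25 <= v <= q75) / (0.5 * m))

    qs = np.ones(m)
    for delta in np.unique(np.abs(ds - dbar)):
        ups = [ds[i] for i in range(m) if ds[i] - dbar[i] >= delta]
        los = [ds[i] for i in range(m) if ds[i] - dbar[i] <= -delta]
        cutup = min(ups) if ups else np.inf
        cutlow = max(los) if los else -np.inf
        called = (d >= cutup) | (d <= cutlow)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        fp = np.median([int(((row >= cutup) | (row <= cutlow)).sum()) for row in perms])
        fdr = min(1.0, pi0 * fp / n_called)
        qs[called] = np.minimum(qs[called], fdr)
    a = np.argsort(np.abs(d), kind="stable")
    qs[a] = np.minimum.accumulate(qs[a])
    return d, np.clip(qs, 0.0, 1.0), pi0


def brute_s0(se, xbar, percentile_grid):
    """Exhaustive scan of the s0 percentile grid (smallest-percentile ties)."""
    se = np.asarray(se, float)
    m = len(se)
    order = np.argsort(se, kind="stable")
    windows = np.array_split(order, min(100, m))
    best = (np.inf, None)
    for pct in sorted(percentile_grid):
        s0 = float(np.percentile(se, pct))
        d = np.asarray(xbar) / (se + s0)
        mads = []
        for w in windows:
            if len(w):
                med = np.median(d[w])
                mads.append(np.median(np.abs(d[w] - med)))
        mads = np.array(mads)
        if mads.mean() == 0:
            continue
        cv = mads.std(ddof=0) / mads.mean()
        if cv < best[0] - 1e-12:
            best = (cv, s0)
    return best[1]


def mw_enumerate_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every group assignment
    of the pooled midranks: P(|U - n1 n2/2| >= |u_obs - n1 n2/2|)."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)

    def rank(v):
        lo = pooled.index(v)
        hi = len(pooled) - 1 - pooled[::-1].index(v)
        return (lo + hi) / 2.0 + 1.0

    ranks = [rank(v) for v in x + y]
    n1, n2 = len(x), len(y)
    base = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    u_obs = sum(ranks[:n1]) - base
    hits = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in idx) - base
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / comb(n1 + n2, n1)


def mw_montecarlo_p(x, y, n_resamples, seed):
    """Monte-Carlo estimate of the two-sided permutation p for U."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, ntot = x.size, x.size + y.size
    ranks = rankdata(np.concatenate([x, y]))
    base = n1 * (n1 + 1) / 2.0
    mu = n1 * y.size / 2.0
    u_obs = ranks[:n1].sum() - base
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 50_000
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        keys = rng.random((b, ntot))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        u = ranks[idx].sum(axis=1) - base
        hits += int(np.count_nonzero(np.abs(u - mu) >= abs(u_obs - mu) - 1e-12))
        done += b
    return (hits + 1) / (n_resamples + 1)
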