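"""One-class Significance Analysis of Microarrays (SAM) on log2 ratios.

Every array in the study is a treatment-vs-common-reference hybridization, so
differential expression of a gene is a one-sample question: is its mean log2
ratio across replicate arrays nonzero? SAM scores each gene with a moderated
t-like statistic d = xbar / (s + s0), where s is the standard error and the
fudge factor s0 damps the inflated d values of genes with tiny variance. The
null distribution is generated by sign-flipping arrays (exhaustively when
2^n <= 4096, otherwise by seeded sampling), and each gene receives a q-value:
the minimum estimated false discovery rate at which it would be called.

The FDR machinery follows the original SAM recipe: for every threshold Delta
over the grid of observed |d - expected order statistic| gaps, asymmetric
upper/lower cutoffs define the called set; the false-positive count is the
median across permutations of permuted d values beyond the cutoffs, scaled by
pi0 estimated from the central quartiles of the pooled permuted d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SamConfig", "SamResult", "one_class_d", "choose_s0",
           "sign_flip_permutations", "q_values", "signed_fold_change", "sam_one_class"]

#: largest permutation count for which sign flips are enumerated exhaustively
EXHAUSTIVE_LIMIT = 4096


@dataclass(frozen=True)
class SamConfig:
    q_threshold: float = 0.05
    s0_percentile_grid: tuple[float, ...] = tuple(range(0, 101, 5))
    n_sampled_permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        if min(self.s0_percentile_grid) < 0 or max(self.s0_percentile_grid) > 100:
            raise ValueError("s0 percentile grid must lie within [0, 100]")


@dataclass
class SamResult:
    """Per-gene SAM summary plus the global nuisance estimates."""

    table: pd.DataFrame  # columns: mean, se, d, q, fold_change
    s0: float
    pi0: float
    permuted_sorted_d: np.ndarray = field(repr=False)  # n_perm x n_genes


def _mean_se(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    if n < 2:
        raise ValueError("one-class SAM needs at least 2 arrays")
    xbar = values.mean(axis=1)
    se = values.std(axis=1, ddof=1) / np.sqrt(n)
    return xbar, se


def one_class_d(values: np.ndarray, s0: float) -> float | np.ndarray:
    """d = xbar / (s + s0) with s the standard error of the mean."""
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    one = np.ndim(values) == 1
    xbar, se = _mean_se(values)
    d = xbar / (se + s0)
    return float(d[0]) if one else d


def choose_s0(se: np.ndarray, xbar: np.ndarray,
              percentile_grid: tuple[float, ...] = tuple(range(0, 101, 5))) -> float:
    """Tusher-style fudge factor: the percentile of s minimizing the
    coefficient of variation of the MAD of d across 100 s-quantile windows,
    ties broken toward the smallest percentile.
    """
    se = np.asarray(se, float)
    xbar = np.asarray(xbar, float)
    m = len(se)
    if m < 10:
        warnings.warn("fewer than 10 genes: s0 selection is unstable", stacklevel=2)
    if np.all(se == 0):
        warnings.warn("all standard errors are zero; using epsilon fudge factor",
                      stacklevel=2)
        return 1e-8
    n_win = min(100, m)
    # assign genes to s-quantile windows
    order = np.argsort(se, kind="stable")
    windows = np.array_split(order, n_win)
    best_cv, best_s0 = np.inf, None
    for pct in sorted(percentile_grid):
        s0 = float(np.percentile(se, pct))
        d = xbar / (se + s0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows
                         if len(w)])
        mu = mads.mean()
        cv = np.inf if mu == 0 else mads.std(ddof=0) / mu
        if cv < best_cv - 1e-12:  # strict improvement => smallest-percentile ties win
            best_cv, best_s0 = cv, s0
    if best_s0 is None:  # every window cv degenerate; fall back to median s
        best_s0 = float(np.percentile(se, 50))
    return best_s0


def _sign_matrix(n: int, config: SamConfig) -> np.ndarray:
    if 2**n <= EXHAUSTIVE_LIMIT:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        return 1.0 - 2.0 * bits  # +1/-1, row 0 = identity
    rng = np.random.default_rng(config.rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_sampled_permutations, n))
    signs[0] = 1.0  # keep the observed labelling in the ensemble
    return signs


def sign_flip_permutations(ratios: np.ndarray, s0: float,
                           config: SamConfig | None = None) -> np.ndarray:
    """Sorted d vectors under the sign-flip null, one row per permutation."""
    config = config or SamConfig()
    ratios = np.asarray(ratios, float)
    n = ratios.shape[1]
    if n < 2:
        raise ValueError("need at least 2 arrays")
    signs = _sign_matrix(n, config)
    out = np.empty((signs.shape[0], ratios.shape[0]))
    for i, sv in enumerate(signs):
        xbar, se = _mean_se(ratios * sv)
        out[i] = np.sort(xbar / (se + s0))
    return out


def _cut_tables(d_sorted: np.ndarray, dbar: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precompute, for binary search over Delta, the upper/lower cut values.

    cutup(Delta)  = min{ d_(i) : d_(i) - dbar_(i) >= Delta }
    cutlow(Delta) = max{ d_(i) : d_(i) - dbar_(i) <= -Delta }
    """
    diff = d_sorted - dbar
    up_order = np.argsort(-diff, kind="stable")
    up_diff = diff[up_order]                     # descending
    up_min_d = np.minimum.accumulate(d_sorted[up_order])
    lo_order = np.argsort(diff, kind="stable")
    lo_diff = diff[lo_order]                     # ascending
    lo_max_d = np.maximum.accumulate(d_sorted[lo_order])
    return up_diff, up_min_d, lo_diff, lo_max_d


def q_values(observed_d: np.ndarray, permuted_sorted: np.ndarray,
             config: SamConfig | None = None) -> tuple[np.ndarray, float]:
    """Per-gene q-values and the pi0 estimate.

    For each Delta on the grid of distinct |d_(i) - dbar_(i)| values the SAM
    asymmetric cut rule defines a called set; FDR(Delta) = pi0 * median
    permuted count beyond the cuts / #called; a gene's q is the minimum
    FDR over the Deltas at which it is called, made monotone in |d| and
    clipped to [0, 1].
    """
    config = config or SamConfig()
    d = np.asarray(observed_d, float)
    m = d.size
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    dbar = permuted_sorted.mean(axis=0)

    # pi0 from the central quartiles of the pooled permuted d
    pooled = permuted_sorted.ravel()
    q25, q75 = np.percentile(pooled, [25, 75])
    pi0 = min(1.0, np.count_nonzero((d >= q25) & (d <= q75)) / (0.5 * m))

    up_diff, up_min_d, lo_diff, lo_max_d = _cut_tables(d_sorted, dbar)
    deltas = np.unique(np.abs(d_sorted - dbar))

    # cut values for every Delta at once
    n_up = np.searchsorted(-up_diff, -deltas, side="right")   # #{diff >= Delta}
    n_lo = np.searchsorted(lo_diff, -deltas, side="right")    # #{diff <= -Delta}
    cutup = np.where(n_up > 0, up_min_d[np.maximum(n_up - 1, 0)], np.inf)
    cutlow = np.where(n_lo > 0, lo_max_d[np.maximum(n_lo - 1, 0)], -np.inf)

    def beyond_cuts(sorted_vals: np.ndarray) -> np.ndarray:
        """#{v >= cutup or v <= cutlow}; the cuts can cross in degenerate
        small-sample geometries, so count the union, not the sum."""
        n_hi = sorted_vals.size - np.searchsorted(sorted_vals, cutup, side="left")
        n_lo = np.searchsorted(sorted_vals, cutlow, side="right")
        overlap = np.maximum(
            0, np.searchsorted(sorted_vals, cutlow, side="right")
            - np.searchsorted(sorted_vals, cutup, side="left"))
        return n_hi + n_lo - overlap

    n_called = beyond_cuts(d_sorted)

    # median permuted count beyond the cuts (permuted rows are already sorted)
    perm_counts = np.stack([beyond_cuts(row) for row in permuted_sorted])
    med_fp = np.median(perm_counts, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_called > 0, pi0 * med_fp / n_called, np.nan)
    fdr = np.clip(fdr, 0.0, 1.0)

    # cutup is non-decreasing and cutlow non-increasing in Delta, so the set of
    # Deltas at which a gene is called is a prefix of the grid; its minimum FDR
    # is a prefix-minimum lookup
    pref = np.minimum.accumulate(np.where(n_called > 0, fdr, np.inf))
    k_up = np.searchsorted(cutup, d, side="right")
    k_lo = np.searchsorted(-cutlow, -d, side="right")
    k = np.maximum(k_up, k_lo)
    q = np.where(k > 0, pref[np.maximum(k - 1, 0)], 1.0)
    q = np.where(np.isfinite(q), q, 1.0)
    # monotone enforcement: q(g) = min estimated FDR over genes no more
    # significant than g (cumulative minimum along ascending |d|)
    a_order = np.argsort(np.abs(d), kind="stable")
    q[a_order] = np.minimum.accumulate(q[a_order])
    return np.clip(q, 0.0, 1.0), pi0


def signed_fold_change(xbar: float | np.ndarray) -> float | np.ndarray:
    """Fold-change convention of the reported tables: 2^x for x >= 0,
    -2^(-x) for x < 0 (a 1.7-fold decrease prints as -1.7)."""
    x = np.asarray(xbar, float)
    fc = np.where(x >= 0, np.exp2(x), -np.exp2(-x))
    return float(fc) if np.ndim(xbar) == 0 else fc


def sam_one_class(ratios: pd.DataFrame | np.ndarray,
                  config: SamConfig | None = None) -> SamResult:
    """Full one-class SAM: s0, permutations, q-values, signed fold changes."""
    config = config or SamConfig()
    if isinstance(ratios, pd.DataFrame):
        genes = ratios.index
        values = ratios.to_numpy(float)
    else:
        values = np.asarray(ratios, float)
        genes = pd.RangeIndex(values.shape[0])
    xbar, se = _mean_se(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s0 = choose_s0(se, xbar, config.s0_percentile_grid)
    d = xbar / (se + s0)
    permuted = sign_flip_permutations(values, s0, config)
    q, pi0 = q_values(d, permuted, config)
    table = pd.DataFrame(
        {"mean": xbar, "se": se, "d": d, "q": q,
         "fold_change": signed_fold_change(xbar)},
        index=genes,
    )
    table.index.name = "gene_id"
    return SamResult(table=table, s0=s0, pi0=pi0, permuted_sorted_d=permuted)
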