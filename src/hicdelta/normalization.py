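"""Normalization offsets for bin-pair counts.

Normalization never alters the counts: every method returns an
OffsetMatrix of per-(bin pair, library) offsets on the natural-log scale
that enter the GLM's linear predictor.  Offsets always include the log
library size; the normalization adjustment on top of it is mean-centred
across libraries for each bin pair, since offsets are only determined up
to a per-bin-pair additive constant.

Methods: loess (trended M-vs-A biases), scaling (a single trimmed-mean
factor per library), CNV (a 2-D smooth of the bin-pair log-FC on the two
marginal-count log-FCs, removing copy-number-driven differences), and
Imakaev-style iterative correction of a dense contact matrix (a
diagnostic/alternative that balances coverage; not chained into offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from statsmodels.nonparametric.smoothers_lowess import lowess

from hicdelta.interaction_counts import CountMatrix, average_abundance, marginal_counts

LN2 = np.log(2.0)


@dataclass
class OffsetMatrix:
    """Per-(bin pair, library) GLM offsets, natural log.

    ``adjustment`` is the normalization part alone (mean-centred across
    libraries per bin pair); ``offsets`` adds log library sizes back.
    """

    adjustment: np.ndarray
    lib_sizes: np.ndarray
    method: str = ""

    def __post_init__(self):
        self.adjustment = np.asarray(self.adjustment, dtype=float)
        if not np.all(np.isfinite(self.adjustment)):
            raise ValueError("offsets must be finite")
        self.adjustment = self.adjustment - self.adjustment.mean(axis=1, keepdims=True)

    @property
    def offsets(self) -> np.ndarray:
        return self.adjustment + np.log(np.asarray(self.lib_sizes, dtype=float))[None, :]


@dataclass
class MAStatistics:
    """MA diagnostics between two libraries: A (log2 CPM) and M (log2 FC)."""

    A: np.ndarray
    M: np.ndarray


def _log2_cpm(countmatrix: CountMatrix, prior: float) -> np.ndarray:
    """Per-library log2 CPM with library-size-scaled prior counts."""
    N = countmatrix.lib_sizes
    prior_i = prior * N / N.mean()
    adj = N + 2 * prior_i
    return np.log2((countmatrix.counts + prior_i[None, :]) / adj[None, :] * 1e6)


def ma_statistics(countmatrix: CountMatrix, lib1: int = 0, lib2: int = 1,
                  prior: float = 2.0) -> MAStatistics:
    """Library-size-adjusted M and A between two libraries."""
    cpm = _log2_cpm(countmatrix, prior)
    return MAStatistics(A=average_abundance(countmatrix, prior), M=cpm[:, lib1] - cpm[:, lib2])


def loess_offsets(countmatrix: CountMatrix, span: float = 0.3, prior: float = 2.0) -> OffsetMatrix:
    """Remove trended (abundance-dependent) biases between libraries.

    For each library, its M-value — log2 CPM minus the across-library mean
    log2 CPM per bin pair — is regressed on the average abundance A with a
    loess curve; the fitted curve is that library's abundance-dependent
    bias and becomes its offset adjustment.  After normalization the
    refitted M-vs-A trend is flat for every pair of libraries.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if countmatrix.n_libs < 2:
        raise ValueError("loess normalization needs at least two libraries")
    cpm = _log2_cpm(countmatrix, prior)
    A = average_abundance(countmatrix, prior)
    M = cpm - cpm.mean(axis=1, keepdims=True)
    adj = np.empty_like(M)
    order_delta = 0.01 * np.ptp(A) if np.ptp(A) > 0 else 0.0
    for i in range(countmatrix.n_libs):
        sm = lowess(M[:, i], A, frac=span, it=0, return_sorted=True, delta=order_delta)
        fit = np.interp(A, sm[:, 0], sm[:, 1])
        # twicing: refit the residuals and add, halving the smoothing bias
        sm2 = lowess(M[:, i] - fit, A, frac=span, it=0, return_sorted=True, delta=order_delta)
        adj[:, i] = fit + np.interp(A, sm2[:, 0], sm2[:, 1])
    return OffsetMatrix(adjustment=adj * LN2, lib_sizes=countmatrix.lib_sizes, method="loess")


def scaling_offsets(countmatrix: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05,
                    prior: float = 2.0) -> OffsetMatrix:
    """One constant factor per library from a doubly trimmed mean of M.

    M values are computed against the across-library mean abundance, then
    bin pairs in the upper/lower ``trim_m`` tails of M and ``trim_a`` tails
    of A are discarded before averaging, TMM-style.  The resulting factors
    are anchored to a geometric mean of one.
    """
    if countmatrix.n_libs < 2:
        raise ValueError("scaling normalization needs at least two libraries")
    # prior-free M values (zero counts excluded) so a pure scaling bias is
    # recovered exactly; the double trim guards against DIs and extremes
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.log2(countmatrix.counts / countmatrix.lib_sizes[None, :])
        ref = logc.mean(axis=1)
        m_all = logc - ref[:, None]
    A = average_abundance(countmatrix, prior)
    a_lo, a_hi = np.quantile(A, [trim_a, 1 - trim_a])
    log_factors = np.empty(countmatrix.n_libs)
    for i in range(countmatrix.n_libs):
        m = m_all[:, i]
        finite = np.isfinite(m)
        if not finite.any():
            raise ValueError("no bin pair observed in every library; cannot scale")
        m_lo, m_hi = np.quantile(m[finite], [trim_m, 1 - trim_m])
        keep = finite & (A >= a_lo) & (A <= a_hi) & (m >= m_lo) & (m <= m_hi)
        if not keep.any():
            raise ValueError("all bin pairs trimmed; loosen the trim fractions")
        log_factors[i] = m[keep].mean()
    log_factors -= log_factors.mean()  # geometric-mean anchor
    adj = np.broadcast_to(log_factors[None, :] * LN2, countmatrix.counts.shape).copy()
    return OffsetMatrix(adjustment=adj, lib_sizes=countmatrix.lib_sizes, method="scaling")


def local_linear_2d(X: np.ndarray, y: np.ndarray, frac: float = 0.3, min_k: int = 30) -> np.ndarray:
    """Local weighted linear regression on two covariates, fitted at the data.

    For each point, the nearest ``max(min_k, frac*n)`` neighbours (Euclidean
    in covariate space) are tricube-weighted by distance and a plane is fit;
    the returned value is the plane evaluated at the point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = min(n, max(min_k, int(np.ceil(frac * n))))
    tree = cKDTree(X)
    dist, idx = tree.query(X, k=k)
    fitted = np.empty(n)
    for i in range(n):
        d, j = dist[i], idx[i]
        dmax = d[-1] if d[-1] > 0 else 1.0
        w = (1 - np.minimum(d / dmax, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-6)
        Z = np.column_stack((np.ones(k), X[j] - X[i]))
        WZ = Z * w[:, None]
        beta, *_ = np.linalg.lstsq(WZ.T @ Z, WZ.T @ y[j], rcond=None)
        fitted[i] = beta[0]
    return fitted


def cnv_offsets(countmatrix: CountMatrix, marginals: np.ndarray | None = None,
                prior: float = 2.0, frac: float = 0.1, min_pairs: int = 200,
                reference: int = 0, smooth_bins: int = 5) -> OffsetMatrix:
    """Remove copy-number-driven biases via multi-dimensional smoothing.

    The marginal count of each bin (reads mapped to it, single-end) proxies
    its genomic coverage; the library-size-adjusted log2 ratio of marginals
    between two libraries is the CNV covariate v_b for that bin.  Each bin
    pair carries the ordered covariate pair (v_bin1, v_bin2) and its own
    log2-FC as response; a local-linear surface of response on covariates is
    the CNV bias and becomes the offset adjustment.  With more than two
    libraries each one is smoothed against the ``reference`` library.

    Because copy-number changes are regional, the per-bin covariate is
    first denoised with a ``smooth_bins``-wide running median along each
    chromosome; set ``smooth_bins=1`` to disable.
    """
    if countmatrix.n_pairs < min_pairs:
        raise ValueError(f"CNV surface needs at least {min_pairs} bin pairs, got {countmatrix.n_pairs}")
    if countmatrix.n_libs < 2:
        raise ValueError("CNV normalization needs at least two libraries")
    if marginals is None:
        marginals = marginal_counts(countmatrix)
    binmap = countmatrix.binmap
    N = countmatrix.lib_sizes
    prior_i = prior * N / N.mean()
    log_marg = np.log2((marginals + prior_i[None, :]) / (2 * N + 4 * prior_i)[None, :])

    keys = countmatrix.keys
    g1 = np.array([binmap.offsets[c] for c in keys["chrom1"]], dtype=np.int64) + keys["bin1"].to_numpy(np.int64)
    g2 = np.array([binmap.offsets[c] for c in keys["chrom2"]], dtype=np.int64) + keys["bin2"].to_numpy(np.int64)
    cpm = _log2_cpm(countmatrix, prior)

    adj = np.zeros_like(cpm)
    for i in range(countmatrix.n_libs):
        if i == reference:
            continue
        v = log_marg[:, i] - log_marg[:, reference]
        if smooth_bins > 1:
            from scipy.ndimage import median_filter
            for chrom in binmap.chromosomes:
                lo = binmap.offsets[chrom]
                hi = lo + binmap.n_bins_of(chrom)
                v[lo:hi] = median_filter(v[lo:hi], size=min(smooth_bins, hi - lo), mode="nearest")
        cov = np.sort(np.column_stack((v[g1], v[g2])), axis=1)  # symmetric in anchors
        resp = cpm[:, i] - cpm[:, reference]
        fitted = local_linear_2d(cov, resp, frac=frac)
        adj[:, i] += fitted * LN2 / 2.0
        adj[:, reference] -= fitted * LN2 / 2.0
    return OffsetMatrix(adjustment=adj, lib_sizes=countmatrix.lib_sizes, method="cnv")


def iterative_correction(matrix: np.ndarray, max_iter: int = 50, tol: float = 1e-6,
                         exclusion_fraction: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Balance a symmetric contact matrix by alternating coverage rescaling.

    Rows and columns are repeatedly divided by their relative coverage
    until the coefficient of variation of the retained nonzero row sums
    drops below ``tol``; the corrected matrix is the original scaled by the
    outer product of reciprocal biases, so retained rows end with equal
    sums.  A fraction of the lowest-coverage bins may be excluded first
    (their bias is NaN and their rows/columns zeroed), as sparse bins make
    the factorization unstable.
    """
    W = np.array(matrix, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.allclose(W, W.T, rtol=1e-8, atol=1e-8):
        raise ValueError("contact matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError("contact matrix must be non-negative")
    if not np.any(W > 0):
        raise ValueError("all-zero contact matrix cannot be balanced")
    if not 0 <= exclusion_fraction < 1:
        raise ValueError("exclusion_fraction must lie in [0, 1)")

    n = W.shape[0]
    coverage = W.sum(axis=0)
    excluded = np.zeros(n, dtype=bool)
    if exclusion_fraction > 0:
        k = int(np.floor(exclusion_fraction * n))
        if k:
            excluded[np.argsort(coverage)[:k]] = True
            W[excluded, :] = 0.0
            W[:, excluded] = 0.0

    bias = np.ones(n)
    for _ in range(max_iter):
        s = W.sum(axis=1)
        live = s > 0
        if not live.any():
            break
        scale = np.ones(n)
        scale[live] = s[live] / s[live].mean()
        bias *= scale
        W /= scale[:, None]
        W /= scale[None, :]
        s = W.sum(axis=1)
        live = s > 0
        cv = s[live].std() / s[live].mean()
        if cv < tol:
            break
    bias[excluded] = np.nan
    return bias, W
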