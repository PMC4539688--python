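"""Abundance filters for bin pairs.

Most of the interaction space is dominated by non-specific ligation and
the generic distance decay of chromatin contacts.  Removing low-abundance
bin pairs before testing enriches for false nulls, lightens the multiple
testing burden and keeps the count models away from their small-count
regime.  Three strategies are provided:

* direct  — threshold on the median abundance of inter-chromosomal bin
  pairs (an estimate of the non-specific ligation rate) times a fold;
* trend   — threshold intra-chromosomal pairs on a loess trend of
  abundance against genomic distance;
* peak    — keep local peaks, pixels enriched over their 2-D neighbourhood.

The filter statistic is the average log2-CPM, which is roughly independent
of the p-value under the null, so filtering does not bias the testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from hicdelta.interaction_counts import CountMatrix, average_abundance, zero_abundance


@dataclass
class FilterDecision:
    keep: np.ndarray
    threshold: float | np.ndarray
    strategy: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)


def _median_with_zeros(values: np.ndarray, n_zero: int, zero_value: float) -> float:
    """Median of ``values`` pooled with ``n_zero`` copies of ``zero_value``.

    Computed analytically so the (possibly enormous) implicit-zero part of
    the universe never has to be materialized.  Assumes every materialized
    value is >= zero_value, which holds because abundance is monotone in
    counts.
    """
    v = np.sort(values)
    n = len(v) + n_zero
    if n == 0:
        raise ValueError("empty universe")

    def kth(k: int) -> float:  # 0-based order statistic of the pooled multiset
        return zero_value if k < n_zero else float(v[k - n_zero])

    if n % 2:
        return kth(n // 2)
    return 0.5 * (kth(n // 2 - 1) + kth(n // 2))


def direct_filter(countmatrix: CountMatrix, fold: float = 5.0, prior: float = 2.0,
                  abundances: np.ndarray | None = None) -> FilterDecision:
    """Keep bin pairs a fold above the non-specific ligation rate.

    The non-specific rate is estimated as the median abundance over the
    FULL inter-chromosomal universe — unobserved inter pairs enter as
    zero-count abundances, counted analytically.  The threshold is that
    median plus log2(fold); the default five-fold matches typical use.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if abundances is None:
        abundances = average_abundance(countmatrix, prior)
    inter = countmatrix.is_inter
    n_inter_universe = countmatrix.n_possible_inter()
    if n_inter_universe == 0:
        raise ValueError("direct filter needs inter-chromosomal bin pairs to estimate non-specific ligation")
    n_zero = n_inter_universe - int(inter.sum())
    med = _median_with_zeros(abundances[inter], n_zero, zero_abundance(countmatrix, prior))
    threshold = med + np.log2(fold)
    return FilterDecision(keep=abundances > threshold, threshold=threshold, strategy="direct",
                          extra={"median_inter": med})


def trend_filter(countmatrix: CountMatrix, fold: float = 1.0, prior: float = 2.0,
                 span: float = 0.25, abundances: np.ndarray | None = None) -> FilterDecision:
    """Keep intra-chromosomal pairs above the abundance-vs-distance trend.

    A loess trend of abundance against log10 genomic distance captures the
    generic distance decay of contact frequency; pairs above their fitted
    value are kept.  Inter-chromosomal pairs, which have no distance, are
    compared against the direct-filter threshold instead.
    """
    if abundances is None:
        abundances = average_abundance(countmatrix, prior)
    intra = ~countmatrix.is_inter
    if intra.sum() < 10:
        raise ValueError("trend filter needs at least 10 intra-chromosomal bin pairs")
    d = np.log10(np.maximum(countmatrix.distances()[intra], 1.0))
    a = abundances[intra]
    fitted_at = np.full(countmatrix.n_pairs, np.nan)
    if np.ptp(d) == 0:
        warnings.warn("all intra-chromosomal distances equal; falling back to the mean abundance threshold")
        fitted_at[intra] = a.mean()
    else:
        sm = lowess(a, d, frac=span, return_sorted=True, delta=0.01 * np.ptp(d))
        fitted_at[intra] = np.interp(d, sm[:, 0], sm[:, 1])
    keep = np.zeros(countmatrix.n_pairs, dtype=bool)
    keep[intra] = abundances[intra] > fitted_at[intra]
    if (~intra).any():
        inter_dec = direct_filter(countmatrix, fold=fold, prior=prior, abundances=abundances)
        keep[~intra] = inter_dec.keep[~intra]
    return FilterDecision(keep=keep, threshold=np.nan, strategy="trend",
                          extra={"fitted": fitted_at})


def _box_sum(sat: np.ndarray, i0, i1, j0, j1):
    """Inclusive box sums from a summed-area table (vectorized)."""
    i0 = np.clip(i0, 0, sat.shape[0] - 2)
    i1 = np.clip(i1, 0, sat.shape[0] - 2)
    j0 = np.clip(j0, 0, sat.shape[1] - 2)
    j1 = np.clip(j1, 0, sat.shape[1] - 2)
    return sat[i1 + 1, j1 + 1] - sat[i0, j1 + 1] - sat[i1 + 1, j0] + sat[i0, j0]


def peak_filter(countmatrix: CountMatrix, radius: int = 2, threshold: float = 0.5,
                prior: float = 2.0) -> tuple[np.ndarray, FilterDecision]:
    """Enrichment of each pixel over its square neighbourhood rings.

    For every materialized bin pair, the mean count over each square ring
    at Chebyshev radius 1..``radius`` (pixel excluded, truncated at the
    edges of the chromosome-pair block and at the diagonal for
    intra-chromosomal blocks) is converted to an abundance; the enrichment
    score is the pixel abundance minus the maximum ring abundance.  Pairs
    whose enrichment exceeds ``threshold`` (log2) are kept.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    binmap = countmatrix.binmap
    keys = countmatrix.keys
    n_libs = countmatrix.n_libs
    pixel_ab = average_abundance(countmatrix, prior)
    enrich = np.full(countmatrix.n_pairs, np.nan)

    groups = keys.groupby(["chrom1", "chrom2"], sort=False).indices
    for (c1, c2), rows in groups.items():
        n1, n2 = binmap.n_bins_of(c1), binmap.n_bins_of(c2)
        if radius >= max(n1, n2):
            raise ValueError(f"radius {radius} exceeds the bin count of chromosome pair ({c1},{c2})")
        intra = c1 == c2
        dense = np.zeros((n1, n2, n_libs))
        b1 = keys["bin1"].to_numpy()[rows]
        b2 = keys["bin2"].to_numpy()[rows]
        dense[b1, b2] = countmatrix.counts[rows]
        valid = np.ones((n1, n2), dtype=bool)
        if intra:
            valid = np.triu(valid)  # canonical pairs live in the upper triangle
            dense[~valid] = 0.0
        sat = np.zeros((n1 + 1, n2 + 1, n_libs))
        sat[1:, 1:] = dense.cumsum(0).cumsum(1)
        vat = np.zeros((n1 + 1, n2 + 1))
        vat[1:, 1:] = valid.astype(float).cumsum(0).cumsum(1)

        best_ab = np.full(len(rows), -np.inf)
        for r in range(1, radius + 1):
            outer_sum = _box_sum(sat, b1 - r, b1 + r, b2 - r, b2 + r)
            inner_sum = _box_sum(sat, b1 - r + 1, b1 + r - 1, b2 - r + 1, b2 + r - 1)
            outer_n = _box_sum(vat, b1 - r, b1 + r, b2 - r, b2 + r)
            inner_n = _box_sum(vat, b1 - r + 1, b1 + r - 1, b2 - r + 1, b2 + r - 1)
            ring_n = outer_n - inner_n
            with np.errstate(invalid="ignore", divide="ignore"):
                ring_mean = (outer_sum - inner_sum) / ring_n[:, None]
            ok = ring_n > 0
            ab = np.full(len(rows), -np.inf)
            if ok.any():
                ab[ok] = average_abundance(countmatrix, prior, counts=ring_mean[ok])
            best_ab = np.maximum(best_ab, ab)
        enrich[rows] = pixel_ab[rows] - best_ab

    decision = FilterDecision(keep=enrich > threshold, threshold=threshold, strategy="peak")
    return enrich, decision
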