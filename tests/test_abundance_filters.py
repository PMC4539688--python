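import numpy as np
import pandas as pd
import pytest

from hicdelta.abundance_filters import (FilterDecision, _median_with_zeros, direct_filter,
                                        peak_filter, trend_filter)
from hicdelta.genome_model import BinMap
from hicdelta.interaction_counts import (CountMatrix, annotate_intervals, average_abundance,
                                         zero_abundance)
from hicdelta.simhic import SimParams, simulate_counts


def _two_chrom_matrix(n_bins=6, seed=0, lib_size=1e5):
    """Fully materialized two-chromosome matrix with random counts."""
    rng = np.random.default_rng(seed)
    bm = BinMap(width=10, boundaries={
        "a": np.arange(0, (n_bins + 1) * 10, 10), "b": np.arange(0, (n_bins + 1) * 10, 10)})
    rows = []
    for c1, c2 in (("a", "a"), ("a", "b"), ("b", "b")):
        if c1 == c2:
            i, j = np.triu_indices(n_bins)
        else:
            i, j = map(np.ravel, np.meshgrid(np.arange(n_bins), np.arange(n_bins), indexing="ij"))
        rows.append(pd.DataFrame({"chrom1": c1, "bin1": i, "chrom2": c2, "bin2": j}))
    keys = annotate_intervals(pd.concat(rows, ignore_index=True), bm)
    counts = rng.integers(0, 40, (len(keys), 2))
    return CountMatrix(keys=keys, counts=counts, lib_sizes=[lib_size, lib_size], binmap=bm)


class TestMedianWithZeros:
    @pytest.mark.parametrize("values,n_zero,zero,expected", [
        ([1, 2, 3], 0, 0.0, 2.0),
        ([1, 2, 3], 3, 0.0, 0.5),       # pooled: 0,0,0,1,2,3
        ([5.0], 4, 1.0, 1.0),           # pooled: 1,1,1,1,5
        ([2.0, 4.0], 2, 1.0, 1.5),      # pooled: 1,1,2,4
    ])
    def test_against_explicit_pooling(self, values, n_zero, zero, expected):
        assert _median_with_zeros(np.array(values, float), n_zero, zero) == expected

    def test_matches_numpy_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            vals = np.sort(rng.uniform(1, 5, rng.integers(1, 8)))
            nz = int(rng.integers(0, 6))
            pooled = np.concatenate([np.zeros(nz), vals])
            assert _median_with_zeros(vals, nz, 0.0) == pytest.approx(np.median(pooled))


class TestDirectFilter:
    def test_threshold_is_inter_median_plus_log2_fold(self):
        cm = _two_chrom_matrix()
        ab = average_abundance(cm)
        inter = cm.is_inter
        dec = direct_filter(cm, fold=2.0)
        med = np.median(ab[inter])  # fully materialized: no implicit zeros
        assert dec.threshold == pytest.approx(med + 1.0)
        assert np.array_equal(dec.keep, ab > dec.threshold)

    def test_fold_one_keeps_above_median(self):
        cm = _two_chrom_matrix()
        dec = direct_filter(cm, fold=1.0)
        ab = average_abundance(cm)
        assert np.array_equal(dec.keep, ab > dec.extra["median_inter"])

    def test_monotone_in_fold(self):
        cm = _two_chrom_matrix()
        k1 = direct_filter(cm, fold=1.0).keep
        k5 = direct_filter(cm, fold=5.0).keep
        assert k5.sum() <= k1.sum() and np.all(k1[k5])

    def test_unmaterialized_zeros_enter_median(self):
        # one chromosome pair materialized out of a large inter universe
        bm = BinMap(width=10, boundaries={"a": np.arange(0, 110, 10),
                                          "b": np.arange(0, 110, 10)})
        keys = annotate_intervals(pd.DataFrame(
            {"chrom1": ["a"], "bin1": [0], "chrom2": ["b"], "bin2": [0]}), bm)
        cm = CountMatrix(keys=keys, counts=np.array([[50, 50]]), lib_sizes=[1e4, 1e4], binmap=bm)
        dec = direct_filter(cm, fold=1.0)
        # 99 of 100 inter pairs are implicit zeros -> median is the zero abundance
        assert dec.extra["median_inter"] == pytest.approx(zero_abundance(cm))

    def test_no_inter_pairs_raises(self):
        bm = BinMap(width=10, boundaries={"a": np.arange(0, 40, 10)})
        keys = annotate_intervals(pd.DataFrame(
            {"chrom1": ["a"], "bin1": [0], "chrom2": ["a"], "bin2": [1]}), bm)
        cm = CountMatrix(keys=keys, counts=np.array([[3, 3]]), lib_sizes=[10.0, 10.0], binmap=bm)
        with pytest.raises(ValueError):
            direct_filter(cm)


class TestTrendFilter:
    def test_flat_trend_keeps_about_half_of_intra(self):
        cm, _ = simulate_counts(SimParams(intra_mean_range=(50.0, 50.0)), seed=3)
        dec = trend_filter(cm)
        intra = ~cm.is_inter
        frac = dec.keep[intra].mean()
        assert 0.35 < frac < 0.65

    def test_spiked_pairs_exceed_decaying_trend(self):
        cm, _ = simulate_counts(SimParams(), seed=4)
        intra = ~cm.is_inter
        d = cm.distances()
        # impose a deterministic power-law decay plus spikes
        mean = 200.0 / (1.0 + d[intra] / 2e6) ** 0.8
        rng = np.random.default_rng(5)
        counts = cm.counts.copy()
        counts[intra] = rng.poisson(np.tile(mean[:, None], (1, cm.n_libs)))
        spike = np.flatnonzero(intra)[rng.choice(intra.sum(), 40, replace=False)]
        counts[spike] *= 8
        cm.counts = counts
        dec = trend_filter(cm)
        assert dec.keep[spike].mean() > 0.95

    def test_too_few_intra_pairs_raises(self):
        cm = _two_chrom_matrix(n_bins=2)
        intra_only = cm.subset(~cm.is_inter)
        with pytest.raises(ValueError):
            trend_filter(intra_only)


class TestPeakFilter:
    @staticmethod
    def _brute_force_enrichment(cm, radius, prior=2.0):
        """Exhaustive neighbourhood scan, independent of the implementation."""
        bm = cm.binmap
        ab = average_abundance(cm, prior)
        dense = {}
        for (c1, c2), rows in cm.keys.groupby(["chrom1", "chrom2"], sort=False).indices.items():
            n1, n2 = bm.n_bins_of(c1), bm.n_bins_of(c2)
            D = np.zeros((n1, n2, cm.n_libs))
            for r in rows:
                D[cm.keys["bin1"].iat[r], cm.keys["bin2"].iat[r]] = cm.counts[r]
            dense[(c1, c2)] = D
        out = np.empty(cm.n_pairs)
        for idx, row in cm.keys.iterrows():
            c1, c2, b1, b2 = row["chrom1"], row["chrom2"], row["bin1"], row["bin2"]
            D = dense[(c1, c2)]
            n1, n2 = D.shape[:2]
            best = -np.inf
            for r in range(1, radius + 1):
                members = []
                for i in range(b1 - r, b1 + r + 1):
                    for j in range(b2 - r, b2 + r + 1):
                        if max(abs(i - b1), abs(j - b2)) != r:
                            continue
                        if not (0 <= i < n1 and 0 <= j < n2):
                            continue
                        if c1 == c2 and i > j:
                            continue
                        members.append(D[i, j])
                if members:
                    ring_mean = np.mean(members, axis=0)
                    best = max(best, average_abundance(cm, prior, counts=ring_mean[None, :])[0])
            out[idx] = ab[idx] - best
        return out

    def test_uniform_field_has_no_enrichment(self):
        cm = _two_chrom_matrix(n_bins=8)
        cm.counts = np.full_like(cm.counts, 7)
        enrich, dec = peak_filter(cm, radius=2, threshold=0.5)
        assert np.allclose(enrich, 0.0, atol=1e-9)
        assert not dec.keep.any()

    def test_single_pixel_on_zero_background(self):
        cm = _two_chrom_matrix(n_bins=8)
        cm.counts = np.zeros_like(cm.counts)
        hit = 10  # an interior pixel
        cm.counts[hit] = 50
        enrich, _ = peak_filter(cm, radius=1)
        ab = average_abundance(cm)
        floor = average_abundance(cm, counts=np.zeros((1, 2)))[0]
        assert enrich[hit] == pytest.approx(ab[hit] - floor)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_8x8_fields(self, seed):
        cm = _two_chrom_matrix(n_bins=8, seed=seed)
        for radius in (1, 2):
            enrich, _ = peak_filter(cm, radius=radius)
            oracle = self._brute_force_enrichment(cm, radius)
            assert np.allclose(enrich, oracle, atol=1e-9)

    def test_threshold_monotonicity(self):
        cm = _two_chrom_matrix(n_bins=8)
        e1, d1 = peak_filter(cm, radius=1, threshold=0.2)
        e2, d2 = peak_filter(cm, radius=1, threshold=0.8)
        assert d2.keep.sum() <= d1.keep.sum() and np.all(d1.keep[d2.keep])

    def test_radius_larger_than_chromosome_raises(self):
        cm = _two_chrom_matrix(n_bins=4)
        with pytest.raises(ValueError):
            peak_filter(cm, radius=5)
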