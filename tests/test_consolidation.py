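import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hicdelta.consolidation import (cluster_bin_pairs, cluster_report, combine_by_group,
                                    nest_bin_pairs, plaid_raster, plot_plaid, simes_combine)
from hicdelta.diff_testing import bh_adjust
from hicdelta.genome_model import BinMap


def _keys(rows):
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])
    return df


def _brute_force_clusters(keys, max_gap):
    """Exhaustive pairwise-adjacency graph components."""
    n = len(keys)
    adj = {i: set() for i in range(n)}

    def gap(s1, e1, s2, e2):
        return max(0, max(s1, s2) - min(e1, e2))

    for i, j in itertools.combinations(range(n), 2):
        a, b = keys.iloc[i], keys.iloc[j]
        if (a["chrom1"], a["chrom2"]) != (b["chrom1"], b["chrom2"]):
            continue
        if gap(a["start1"], a["end1"], b["start1"], b["end1"]) <= max_gap and \
           gap(a["start2"], a["end2"], b["start2"], b["end2"]) <= max_gap:
            adj[i].add(j)
            adj[j].add(i)
    seen, comp = {}, 0
    for i in range(n):
        if i in seen:
            continue
        stack = [i]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen[k] = comp
            stack.extend(adj[k])
        comp += 1
    return np.array([seen[i] for i in range(n)])


class TestClusterBinPairs:
    def test_shared_anchor_adjacent_other_is_one_cluster(self):
        keys = _keys([("c", 0, 10, "c", 20, 30), ("c", 0, 10, "c", 30, 40)])
        assert len(set(cluster_bin_pairs(keys, max_gap=0))) == 1

    def test_diagonal_chain_is_transitive(self):
        keys = _keys([("c", 0, 10, "c", 0, 10), ("c", 10, 20, "c", 10, 20),
                      ("c", 20, 30, "c", 20, 30)])
        ids = cluster_bin_pairs(keys, max_gap=0)
        assert len(set(ids)) == 1

    def test_distinct_chromosome_pairs_never_link(self):
        keys = _keys([("a", 0, 10, "a", 0, 10), ("a", 0, 10, "b", 0, 10)])
        assert len(set(cluster_bin_pairs(keys, max_gap=10**9))) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            cluster_bin_pairs(_keys([("c", 0, 10, "c", 0, 10)]), max_gap=-1)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["a", "b"]), st.integers(0, 12),
                              st.integers(0, 12)), min_size=1, max_size=30),
           st.integers(0, 3))
    def test_matches_brute_force_components(self, raw, max_gap):
        rows = []
        for chrom, i, j in raw:
            i, j = min(i, j), max(i, j)
            rows.append((chrom, i * 5, i * 5 + 5, chrom, j * 5, j * 5 + 5))
        keys = _keys(rows)
        got = cluster_bin_pairs(keys, max_gap=max_gap)
        want = _brute_force_clusters(keys, max_gap)
        # compare partitions, not label values (bijection between labellings)
        fwd, rev = {}, {}
        for g, w in zip(got, want):
            assert fwd.setdefault(g, w) == w
            assert rev.setdefault(w, g) == g

    def test_order_invariant_and_monotone_in_gap(self):
        rng = np.random.default_rng(0)
        rows = [("c", int(i) * 5, int(i) * 5 + 5, "c", int(j) * 5, int(j) * 5 + 5)
                for i, j in rng.integers(0, 15, (25, 2))]
        keys = _keys(rows)
        perm = rng.permutation(len(keys))
        a = cluster_bin_pairs(keys, 5)
        b = cluster_bin_pairs(keys.iloc[perm].reset_index(drop=True), 5)
        assert len(set(a)) == len(set(b))
        assert len(set(cluster_bin_pairs(keys, 10))) <= len(set(a))


class TestNestBinPairs:
    def _parent(self):
        return BinMap(width=1_000_000, boundaries={"c": np.array([0, 1_000_000, 2_000_000])})

    def test_small_pairs_map_by_midpoint(self):
        small = _keys([("c", 0, 20_000, "c", 20_000, 40_000),
                       ("c", 980_000, 1_000_000, "c", 1_000_000, 1_020_000)])
        small[["chrom1", "chrom2"]] = small[["chrom1", "chrom2"]]
        parents = nest_bin_pairs(small, self._parent())
        assert parents[["bin1", "bin2"]].values.tolist() == [[0, 0], [0, 1]]

    def test_identical_bin_size_self_parent(self):
        parent = self._parent()
        small = _keys([("c", 0, 1_000_000, "c", 1_000_000, 2_000_000)])
        parents = nest_bin_pairs(small, parent)
        assert parents[["bin1", "bin2"]].values.tolist() == [[0, 1]]

    def test_midpoint_outside_parent_raises(self):
        small = _keys([("c", 2_000_000, 2_020_000, "c", 2_000_000, 2_020_000)])
        with pytest.raises(ValueError):
            nest_bin_pairs(small, self._parent())


class TestSimesCombine:
    def test_single_p_identity(self):
        assert simes_combine([0.2]) == 0.2

    def test_hand_evaluation(self):
        assert simes_combine([0.01, 0.04]) == pytest.approx(0.02)

    def test_equal_ps_unchanged(self):
        assert simes_combine([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            simes_combine([])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_bounds_and_exhaustive_formula(self, ps):
        got = simes_combine(ps)
        p = np.sort(ps)
        want = min(1.0, min(len(p) * v / (i + 1) for i, v in enumerate(p)))
        assert got == pytest.approx(want)
        assert min(ps) - 1e-9 <= got <= min(1.0, len(ps) * min(ps)) + 1e-9


class TestCombineByGroup:
    def test_bh_applied_across_groups(self):
        ids = np.array([0, 0, 1, 2])
        p = np.array([0.01, 0.04, 0.5, 0.9])
        lf = np.array([2.0, 1.0, -1.0, 0.5])
        out = combine_by_group(ids, p, lf)
        assert len(out) == 3
        assert out.loc[out["group"] == 0, "pvalue"].iloc[0] == pytest.approx(0.02)
        assert out.loc[out["group"] == 0, "logFC"].iloc[0] == 2.0  # member with smallest p
        assert np.allclose(out["fdr"], bh_adjust(out["pvalue"].to_numpy()))

    def test_cluster_report_bounding_boxes(self):
        keys = pd.DataFrame({
            "chrom1": ["c", "c"], "bin1": [0, 1], "chrom2": ["c", "c"], "bin2": [2, 3],
            "start1": [0, 10], "end1": [10, 20], "start2": [20, 30], "end2": [30, 40]})
        rep = cluster_report(keys, np.array([0.01, 0.02]), np.array([1.0, 2.0]), max_gap=0)
        assert len(rep) == 1
        row = rep.iloc[0]
        assert (row["start1"], row["end1"], row["start2"], row["end2"]) == (1, 20, 21, 40)


class TestPlaid:
    def test_zero_pairs_blank_raster(self):
        grid, *_ = plaid_raster([], ("c", 0, 100), ("c", 0, 100), pixel=10)
        assert grid.shape == (10, 10) and grid.sum() == 0

    def test_single_pair_single_pixel(self):
        grid, *_ = plaid_raster([("c", 35, "c", 77)], ("c", 0, 100), ("c", 0, 100), pixel=10)
        assert grid[3, 7] == 1 and grid.sum() == 1

    def test_library_size_scales_intensity(self):
        pairs = [("c", 35, "c", 77)]
        g1, *_ = plaid_raster(pairs, ("c", 0, 100), ("c", 0, 100), 10, lib_size=1.0)
        g2, *_ = plaid_raster(pairs, ("c", 0, 100), ("c", 0, 100), 10, lib_size=2.0)
        assert g2[3, 7] == pytest.approx(g1[3, 7] / 2)

    def test_plot_returns_axes(self):
        import matplotlib
        matplotlib.use("Agg")
        ax = plot_plaid([("c", 35, "c", 77)], ("c", 0, 100), ("c", 0, 100), pixel=10)
        assert ax is not None
        ax2 = plot_plaid([("c", 35, "c", 77)], ("c", 0, 100), ("c", 0, 100), pixel=10,
                         rotate=True)
        assert ax2 is not None
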