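"""Consolidate differential-interaction results and visualize them.

A genuine differential interaction usually lights up several adjacent bin
pairs, and analyses run at several bin sizes detect it redundantly.  Two
remedies are provided: clustering of adjacent bin pairs in the interaction
space (single linkage under Chebyshev adjacency), and nesting of
small-bin-pair results within parent bin pairs from a coarser analysis.
Evidence within a cluster or parent is combined with Simes' method, and
the combined p-values are BH-adjusted so one FDR is reported per event.
Plaid plots render read-pair density over a rectangle of the interaction
space for visual inspection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hicdelta.diff_testing import bh_adjust
from hicdelta.genome_model import BinMap


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _interval_gap(s1, e1, s2, e2) -> int:
    """Gap between two half-open intervals; 0 if they touch or overlap."""
    return max(0, max(s1, s2) - min(e1, e2))


def cluster_bin_pairs(keys: pd.DataFrame, max_gap: int = 0) -> np.ndarray:
    """Single-linkage clusters of bin pairs adjacent in the interaction space.

    Two bin pairs link iff they share a chromosome pair and BOTH anchor
    intervals are within ``max_gap`` bp of each other (Chebyshev adjacency
    in 2-D); components are closed transitively.  Ids are assigned by the
    sorted position of each cluster's first member, so the labelling is
    deterministic and order-invariant.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    n = len(keys)
    uf = _UnionFind(n)
    cols = ["start1", "end1", "start2", "end2"]
    for _, rows in keys.groupby(["chrom1", "chrom2"], sort=False).indices.items():
        sub = keys.iloc[rows][cols].to_numpy()
        order = np.argsort(sub[:, 0], kind="stable")
        sub = sub[order]
        ridx = np.asarray(rows)[order]
        for a in range(len(ridx)):
            s1a, e1a, s2a, e2a = sub[a]
            for b in range(a + 1, len(ridx)):
                s1b, e1b, s2b, e2b = sub[b]
                if s1b - e1a > max_gap:  # sorted by start1: no later b can link
                    break
                if (_interval_gap(s1a, e1a, s1b, e1b) <= max_gap
                        and _interval_gap(s2a, e2a, s2b, e2b) <= max_gap):
                    uf.union(int(ridx[a]), int(ridx[b]))
    roots = np.array([uf.find(i) for i in range(n)])
    _, ids = np.unique(roots, return_inverse=True)
    return ids


def nest_bin_pairs(small_keys: pd.DataFrame, parent_binmap: BinMap) -> pd.DataFrame:
    """Assign each small bin pair to the parent bin pair containing it.

    A small pair maps to the parent whose anchor bins contain its anchor
    midpoints; with canonical re-ordering every small pair gets exactly one
    parent.  Returns a DataFrame of parent keys aligned with ``small_keys``.
    """
    rows = []
    for _, r in small_keys.iterrows():
        mid1 = (r["start1"] + r["end1"]) // 2
        mid2 = (r["start2"] + r["end2"]) // 2
        try:
            p1 = parent_binmap.bin_of(r["chrom1"], int(mid1))
            p2 = parent_binmap.bin_of(r["chrom2"], int(mid2))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"anchor midpoint outside the parent bin map: {exc}") from exc
        c1, b1, c2, b2 = r["chrom1"], p1, r["chrom2"], p2
        if (c1, b1) > (c2, b2):
            c1, b1, c2, b2 = c2, b2, c1, b1
        s1, e1 = parent_binmap.bin_interval(c1, b1)
        s2, e2 = parent_binmap.bin_interval(c2, b2)
        rows.append((c1, b1, c2, b2, s1, e1, s2, e2))
    return pd.DataFrame(rows, columns=["chrom1", "bin1", "chrom2", "bin2",
                                       "start1", "end1", "start2", "end2"])


def simes_combine(pvalues) -> float:
    """Simes' combined p-value: min over i of n * p_(i) / i."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    n = len(p)
    return float(min(1.0, np.min(n * p / np.arange(1, n + 1))))


def combine_by_group(group_ids: np.ndarray, pvalues: np.ndarray,
                     logfc: np.ndarray | None = None) -> pd.DataFrame:
    """Simes-combine p-values within groups (clusters or parents) + BH.

    Returns one row per group: combined p, BH-adjusted FDR across groups,
    member count, and the representative logFC (member with smallest p).
    """
    df = pd.DataFrame({"group": group_ids, "p": pvalues})
    if logfc is not None:
        df["logFC"] = logfc
    out = []
    for gid, sub in df.groupby("group", sort=True):
        rec = {"group": gid, "n_members": len(sub), "pvalue": simes_combine(sub["p"].to_numpy())}
        if logfc is not None:
            rec["logFC"] = float(sub.loc[sub["p"].idxmin(), "logFC"])
        out.append(rec)
    table = pd.DataFrame(out)
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return table


def cluster_report(keys: pd.DataFrame, pvalues: np.ndarray, logfc: np.ndarray,
                   max_gap: int = 0) -> pd.DataFrame:
    """Cluster adjacent bin pairs and report one combined row per cluster.

    The bounding box covers all member anchor intervals; coordinates are
    reported 1-based inclusive.
    """
    ids = cluster_bin_pairs(keys, max_gap=max_gap)
    combined = combine_by_group(ids, pvalues, logfc).set_index("group")
    rows = []
    for gid in np.unique(ids):
        sub = keys.loc[ids == gid]
        rows.append({
            "cluster": int(gid),
            "chrom1": sub["chrom1"].iloc[0],
            "start1": int(sub["start1"].min()) + 1,
            "end1": int(sub["end1"].max()),
            "chrom2": sub["chrom2"].iloc[0],
            "start2": int(sub["start2"].min()) + 1,
            "end2": int(sub["end2"].max()),
            "n_members": int(combined.loc[gid, "n_members"]),
            "logFC": combined.loc[gid, "logFC"],
            "pvalue": combined.loc[gid, "pvalue"],
            "fdr": combined.loc[gid, "fdr"],
        })
    return pd.DataFrame(rows)


def plaid_raster(pairs, region1, region2, pixel: int, lib_size: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Count read pairs into pixel x pixel boxes over a rectangle.

    ``pairs`` is an iterable of (chrom1, pos1, chrom2, pos2); both
    orderings of a pair are checked against (region1, region2).  Counts
    are divided by ``lib_size`` so plots from libraries of different depth
    are comparable.
    """
    c1, s1, e1 = region1
    c2, s2, e2 = region2
    edges1 = np.arange(s1, e1 + pixel, pixel, dtype=float)
    edges2 = np.arange(s2, e2 + pixel, pixel, dtype=float)
    grid = np.zeros((len(edges1) - 1, len(edges2) - 1))
    for pc1, p1, pc2, p2 in pairs:
        for (qc1, q1, qc2, q2) in ((pc1, p1, pc2, p2), (pc2, p2, pc1, p1)):
            if qc1 == c1 and qc2 == c2 and s1 <= q1 < e1 and s2 <= q2 < e2:
                grid[int((q1 - s1) // pixel), int((q2 - s2) // pixel)] += 1
                break
    return grid / lib_size, edges1, edges2


def plot_plaid(pairs, region1, region2, pixel: int, lib_size: float = 1.0,
               ax=None, rotate: bool = False, cmap: str = "Blues", vmax=None):
    """Plaid plot: heat map of library-size-adjusted read-pair counts.

    With ``rotate=True`` the raster is drawn at 45 degrees, which is the
    conventional view for near-diagonal (intra-chromosomal) regions.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    grid, e1, e2 = plaid_raster(pairs, region1, region2, pixel, lib_size)
    if ax is None:
        _, ax = plt.subplots()
    if rotate:
        from matplotlib.transforms import Affine2D
        tr = Affine2D().rotate_deg(-45) + ax.transData
        im = ax.pcolormesh(*np.meshgrid(e1, e2, indexing="ij"), grid, cmap=cmap,
                           vmax=vmax, transform=tr)
        ax.set_aspect("auto")
        ax.autoscale()
    else:
        im = ax.imshow(grid.T, origin="lower", cmap=cmap, vmax=vmax, aspect="auto",
                       extent=(e1[0], e1[-1], e2[0], e2[-1]))
    ax.set_xlabel(f"{region1[0]} position (bp)")
    ax.set_ylabel(f"{region2[0]} position (bp)")
    ax.figure.colorbar(im, ax=ax, label="read pairs / library size")
    return ax
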