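"""Summarize Hi-C read pairs into bin-pair counts across libraries.

The interaction space — all canonical pairs of genomic bins — is the unit
of analysis: the count for bin pair b in library i, y_bi, is the number of
read pairs with one read in each bin.  Only observed bin pairs are
materialized (the space is quadratic in genome size); unobserved pairs are
implicit zeros, and the possible-pair universe sizes are tracked so that
downstream filters can reason about them without materialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hicdelta.genome_model import BinMap

KEY_COLUMNS = ["chrom1", "bin1", "chrom2", "bin2"]


@dataclass
class CountMatrix:
    """Bin pairs x libraries integer counts, plus the bin-pair annotation.

    Attributes
    ----------
    keys : DataFrame
        One row per materialized bin pair: chrom1, bin1, chrom2, bin2
        (within-chromosome bin indices, canonical upper-triangle order)
        and the bin intervals start1..end2.
    counts : (n_pairs, n_libs) int array
        y_bi.
    lib_sizes : (n_libs,) array
        Total retained read pairs per library (>= column sums, since
        zero-count pairs may be unlisted and chromosomes excluded).
    binmap : BinMap
        The bin definition shared by all libraries.
    """

    keys: pd.DataFrame
    counts: np.ndarray
    lib_sizes: np.ndarray
    binmap: BinMap
    lib_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if len(self.keys) != self.counts.shape[0]:
            raise ValueError("keys and counts disagree on the number of bin pairs")
        if not self.lib_names:
            self.lib_names = [f"lib{i + 1}" for i in range(self.n_libs)]

    @property
    def n_pairs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libs(self) -> int:
        return self.counts.shape[1]

    @property
    def is_inter(self) -> np.ndarray:
        return (self.keys["chrom1"] != self.keys["chrom2"]).to_numpy()

    def distances(self) -> np.ndarray:
        """Genomic distance between bin midpoints; NaN for inter-chromosomal."""
        mid1 = (self.keys["start1"] + self.keys["end1"]).to_numpy() / 2.0
        mid2 = (self.keys["start2"] + self.keys["end2"]).to_numpy() / 2.0
        d = np.abs(mid2 - mid1)
        d[self.is_inter] = np.nan
        return d

    # -- possible-pair universe (implicit zeros included) ------------------
    def n_possible_intra(self) -> int:
        return sum(n * (n + 1) // 2 for n in (self.binmap.n_bins_of(c) for c in self.binmap.chromosomes))

    def n_possible_inter(self) -> int:
        ns = [self.binmap.n_bins_of(c) for c in self.binmap.chromosomes]
        total = sum(ns)
        return sum(n * (total - n) for n in ns) // 2

    def subset(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            keys=self.keys.loc[mask].reset_index(drop=True),
            counts=self.counts[mask],
            lib_sizes=self.lib_sizes,
            binmap=self.binmap,
            lib_names=list(self.lib_names),
        )

    def to_tsv(self, path, extra: pd.DataFrame | None = None) -> None:
        """Write counts as TSV with 1-based inclusive coordinates."""
        out = self.keys.copy()
        out["start1"] += 1
        out["start2"] += 1
        for i, name in enumerate(self.lib_names):
            out[f"count_{name}"] = self.counts[:, i]
        if extra is not None:
            out = pd.concat([out, extra.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)

    def to_bedpe(self, path) -> None:
        bed = self.keys[["chrom1", "start1", "end1", "chrom2", "start2", "end2"]].copy()
        bed["name"] = [f"bp{i}" for i in range(len(bed))]
        bed["score"] = self.counts.sum(axis=1)
        bed.to_csv(path, sep="\t", index=False, header=False)


def _canonical_key(chrom1: str, bin1: int, chrom2: str, bin2: int) -> tuple:
    if (chrom1, bin1) > (chrom2, bin2):
        return chrom2, bin2, chrom1, bin1
    return chrom1, bin1, chrom2, bin2


def count_pairs(pair_stores, binmap: BinMap, lib_names: list[str] | None = None) -> CountMatrix:
    """Count read pairs into canonical bin pairs, one column per library.

    ``pair_stores`` is a sequence of libraries, each either a PairStore or
    an iterable of PairRecord.  Every pair increments exactly one bin pair;
    pairs with both reads in one bin increment that diagonal key once.
    Bin pairs never observed in any library are omitted (implicit zeros).
    """
    from hicdelta.pair_processing import PairRecord, PairStore

    tallies: dict[tuple, np.ndarray] = {}
    n_libs = len(pair_stores)
    lib_sizes = np.zeros(n_libs)

    def add(lib: int, chrom1: str, pos1: int, chrom2: str, pos2: int):
        try:
            b1 = binmap.bin_of(chrom1, pos1)
            b2 = binmap.bin_of(chrom2, pos2)
        except KeyError as exc:
            raise ValueError(f"chromosome {exc} absent from the bin map") from exc
        key = _canonical_key(chrom1, b1, chrom2, b2)
        if key not in tallies:
            tallies[key] = np.zeros(n_libs, dtype=np.int64)
        tallies[key][lib] += 1
        lib_sizes[lib] += 1

    for i, store in enumerate(pair_stores):
        if isinstance(store, PairStore):
            for c1, c2, table in store.iter_pairs():
                for pos1, pos2 in table[:, :2]:
                    add(i, c1, int(pos1), c2, int(pos2))
        else:
            for p in store:
                add(i, p.anchor1.chrom, p.anchor1.position, p.anchor2.chrom, p.anchor2.position)

    order = sorted(tallies)
    keys = pd.DataFrame(order, columns=KEY_COLUMNS) if order else pd.DataFrame(columns=KEY_COLUMNS)
    counts = np.vstack([tallies[k] for k in order]) if order else np.zeros((0, n_libs), dtype=np.int64)
    keys = annotate_intervals(keys, binmap)
    return CountMatrix(keys=keys, counts=counts, lib_sizes=lib_sizes, binmap=binmap,
                       lib_names=lib_names or [])


def annotate_intervals(keys: pd.DataFrame, binmap: BinMap) -> pd.DataFrame:
    keys = keys.copy()
    for side in ("1", "2"):
        starts, ends = [], []
        for chrom, b in zip(keys[f"chrom{side}"], keys[f"bin{side}"]):
            s, e = binmap.bin_interval(chrom, int(b))
            starts.append(s)
            ends.append(e)
        keys[f"start{side}"] = pd.Series(starts, dtype=np.int64)
        keys[f"end{side}"] = pd.Series(ends, dtype=np.int64)
    return keys


def marginal_counts(countmatrix: CountMatrix) -> np.ndarray:
    """Per-bin read counts per library, treating each pair as two single reads.

    A diagonal bin pair contributes 2 to its bin, an off-diagonal pair 1 to
    each anchor bin; marginals therefore sum to twice the counted pairs.
    They proxy genomic coverage, hence copy number, for CNV normalization.
    """
    binmap = countmatrix.binmap
    out = np.zeros((binmap.n_bins, countmatrix.n_libs), dtype=np.int64)
    k = countmatrix.keys
    g1 = np.array([binmap.offsets[c] for c in k["chrom1"]], dtype=np.int64) + k["bin1"].to_numpy(np.int64) if len(k) else np.array([], dtype=np.int64)
    g2 = np.array([binmap.offsets[c] for c in k["chrom2"]], dtype=np.int64) + k["bin2"].to_numpy(np.int64) if len(k) else np.array([], dtype=np.int64)
    for lib in range(countmatrix.n_libs):
        np.add.at(out[:, lib], g1, countmatrix.counts[:, lib])
        np.add.at(out[:, lib], g2, countmatrix.counts[:, lib])
    return out


def average_abundance(countmatrix: CountMatrix, prior: float = 2.0,
                      counts: np.ndarray | None = None) -> np.ndarray:
    """Average log2 counts-per-million per bin pair (the filter statistic).

    The prior count is scaled per library in proportion to library size
    (so a deeper library gets a proportionally larger prior) and the
    library sizes are adjusted by twice the scaled prior, keeping the
    statistic finite at zero counts and scale-invariant:

        A_b = log2( mean_i(y_bi + prior_i) / mean_i(N_i + 2 prior_i) * 1e6 )
    """
    if prior < 0:
        raise ValueError("prior count must be non-negative")
    if counts is None:
        counts = countmatrix.counts
    N = countmatrix.lib_sizes
    prior_i = prior * N / N.mean()
    adj_libsize = N + 2 * prior_i
    mean_count = (counts + prior_i[None, :]).mean(axis=1)
    return np.log2(mean_count / adj_libsize.mean() * 1e6)


def zero_abundance(countmatrix: CountMatrix, prior: float = 2.0) -> float:
    """Abundance of an unmaterialized (all-zero) bin pair."""
    N = countmatrix.lib_sizes
    prior_i = prior * N / N.mean()
    adj = N + 2 * prior_i
    return float(np.log2(prior_i.mean() / adj.mean() * 1e6))


def exclude_chromosomes(countmatrix: CountMatrix, names) -> CountMatrix:
    """Drop every bin pair with either anchor on a named chromosome.

    Useful for removing chrY before a differential analysis across
    conditions with different sexes.  Unknown names warn and are ignored.
    Library sizes are left untouched: they reflect total retained pairs.
    """
    import warnings

    known = set(countmatrix.binmap.chromosomes)
    wanted = set()
    for name in names:
        if name in known:
            wanted.add(name)
        else:
            warnings.warn(f"chromosome {name!r} not present; ignoring")
    if not wanted:
        return countmatrix
    mask = ~(countmatrix.keys["chrom1"].isin(wanted) | countmatrix.keys["chrom2"].isin(wanted)).to_numpy()
    return countmatrix.subset(mask)
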