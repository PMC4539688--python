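"""End-to-end orchestration: prepare -> count -> filter -> normalize -> test -> report.

No new computation lives here; each stage calls the corresponding library
module, persists its intermediate, and logs counts in and out so a run can
be audited.  Configuration is a plain dataclass loadable from YAML, echoed
into every output header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hicdelta.genome_model import BinMap, Enzyme, FragmentMap, build_bins
from hicdelta.pair_processing import PairStore, classify_and_filter, load_name_sorted_pairs
from hicdelta.interaction_counts import CountMatrix, average_abundance, count_pairs, exclude_chromosomes
from hicdelta.abundance_filters import direct_filter, peak_filter, trend_filter
from hicdelta.normalization import cnv_offsets, loess_offsets, scaling_offsets
from hicdelta.diff_testing import (design_matrix, estimate_dispersion_trend, fit_nb_glm,
                                   ql_dispersions, ql_f_test)
from hicdelta.consolidation import cluster_report, combine_by_group, nest_bin_pairs

log = logging.getLogger("hicdelta")


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    enzyme: str = "AAGCTT:1"
    bin_sizes: list[int] = field(default_factory=lambda: [1_000_000])
    min_mapq: int = 10
    max_frag: int = 600
    min_inward: int = 1000
    min_outward: int = 25000
    filter_strategy: str = "direct"
    filter_fold: float = 5.0
    peak_radius: int = 2
    normalization: str = "loess"
    span: float = 0.3
    exclude: list[str] = field(default_factory=list)
    fdr: float = 0.05
    cluster_gap: int = 0
    seed: int = 0

    def __post_init__(self):
        Enzyme.from_string(self.enzyme)  # validate early
        if any(b < 1 for b in self.bin_sizes):
            raise ValueError("bin sizes must be positive")
        if self.filter_strategy not in ("direct", "trend", "peak"):
            raise ValueError(f"unknown filter strategy {self.filter_strategy!r}")
        if self.normalization not in ("loess", "scale", "cnv", "none"):
            raise ValueError(f"unknown normalization method {self.normalization!r}")
        if not 0 < self.fdr < 1:
            raise ValueError("FDR threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def header_lines(self) -> list[str]:
        return [f"# hicdelta config: {json.dumps(asdict(self), sort_keys=True)}"]


def _write_tsv(df: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        for line in config.header_lines():
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def prepare_library(sam_path, fragmap: FragmentMap, config: RunConfig, out_path) -> PairStore:
    """QC one name-sorted SAM/BAM into a pair store."""
    pairs = load_name_sorted_pairs(sam_path)
    kept, stats = classify_and_filter(pairs, fragmap, min_mapq=config.min_mapq,
                                      max_frag=config.max_frag, min_inward=config.min_inward,
                                      min_outward=config.min_outward)
    store = PairStore(out_path)
    store.write(kept, stats=stats)
    log.info("prepare %s: %d pairs in, %d retained", sam_path, stats.total, stats.retained)
    return store


def run_pipeline(config: RunConfig, sam_files: dict[str, str], groups: dict[str, str],
                 genome_fasta: str, outdir) -> dict:
    """Run every stage; returns a bundle of file paths and result tables.

    ``sam_files`` maps library name -> name-sorted SAM/BAM path; ``groups``
    maps library name -> condition label.  With several bin sizes the
    finest analyses are nested into the largest-bin parents and combined.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enzyme = Enzyme.from_string(config.enzyme)
    fragmap = FragmentMap.from_fasta(genome_fasta, enzyme)
    lib_names = list(sam_files)
    group_labels = [groups[n] for n in lib_names]

    stores = []
    for name in lib_names:
        store = prepare_library(sam_files[name], fragmap, config, outdir / f"{name}.pairs.h5")
        stores.append(store)

    bundle: dict = {"config": config, "per_binsize": {}}
    per_size_results = {}
    for width in sorted(config.bin_sizes, reverse=True):
        binmap = build_bins(fragmap, width)
        cm = count_pairs(stores, binmap, lib_names=lib_names)
        if config.exclude:
            cm = exclude_chromosomes(cm, config.exclude)
        n_counted = int(cm.counts.sum())
        log.info("count @%d bp: %d bin pairs, %d read pairs", width, cm.n_pairs, n_counted)

        if config.filter_strategy == "direct":
            decision = direct_filter(cm, fold=config.filter_fold)
        elif config.filter_strategy == "trend":
            decision = trend_filter(cm)
        else:
            _, decision = peak_filter(cm, radius=config.peak_radius)
        filtered = cm.subset(decision.keep)
        log.info("filter @%d bp (%s): %d -> %d bin pairs", width, config.filter_strategy,
                 cm.n_pairs, filtered.n_pairs)
        if filtered.n_pairs == 0:
            raise RuntimeError(f"stage filter @{width} bp removed every bin pair")

        if config.normalization == "loess":
            off = loess_offsets(filtered, span=config.span)
        elif config.normalization == "scale":
            off = scaling_offsets(filtered)
        elif config.normalization == "cnv":
            off = cnv_offsets(filtered)
        else:
            off = scaling_offsets(filtered, trim_m=0.5)  # depth-only fallback
        X, labels = design_matrix(group_labels)
        abundance = average_abundance(filtered)
        disp = estimate_dispersion_trend(filtered.counts, X, off.offsets, abundance=abundance)
        fit = fit_nb_glm(filtered.counts, X, off.offsets, disp.trended, labels=labels)
        ql = ql_dispersions(fit, abundance)
        contrast = np.zeros(X.shape[1])
        contrast[1] = 1.0
        res = ql_f_test(fit, ql, contrast)
        table = pd.concat([filtered.keys.reset_index(drop=True), res.table], axis=1)
        _write_tsv(table, outdir / f"results_{width}.tsv", config)
        per_size_results[width] = (filtered, res)
        bundle["per_binsize"][width] = {"counts": filtered, "results": table,
                                        "dispersion": disp, "ql": ql,
                                        "path": outdir / f"results_{width}.tsv"}
        clusters = cluster_report(filtered.keys, res["pvalue"], res["logFC"],
                                  max_gap=config.cluster_gap)
        _write_tsv(clusters, outdir / f"clusters_{width}.tsv", config)
        bundle["per_binsize"][width]["clusters"] = clusters

    if len(config.bin_sizes) > 1:
        widths = sorted(per_size_results, reverse=True)
        parent_width = widths[0]
        parent_binmap = per_size_results[parent_width][0].binmap
        frames = []
        for width in widths:
            filtered, res = per_size_results[width]
            if width == parent_width:
                parents = filtered.keys[["chrom1", "bin1", "chrom2", "bin2"]]
            else:
                parents = nest_bin_pairs(filtered.keys, parent_binmap)[["chrom1", "bin1", "chrom2", "bin2"]]
            frames.append(pd.DataFrame({
                "parent": [f"{c1}:{b1}|{c2}:{b2}" for c1, b1, c2, b2 in parents.itertuples(index=False)],
                "p": res["pvalue"], "logFC": res["logFC"],
            }))
        pooled = pd.concat(frames, ignore_index=True)
        consolidated = combine_by_group(pooled["parent"].to_numpy(), pooled["p"].to_numpy(),
                                        pooled["logFC"].to_numpy())
        _write_tsv(consolidated, outdir / "consolidated.tsv", config)
        bundle["consolidated"] = consolidated
    return bundle
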