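"""Shared fixtures: a small synthetic genome, its HindIII digest, and a
hand-built name-sorted SAM exercising every QC removal cause."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from hypothesis import settings

from hicdelta.genome_model import Enzyme, FragmentMap

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

HINDIII = Enzyme("AAGCTT", 1)


def _chromosome_with_sites(length: int, period: int, seed: int) -> str:
    """Random sequence whose ONLY AAGCTT sites start at k*period + (period-6),
    i.e. cut centres at k*period + (period-3)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    while "AAGCTT" in seq:
        seq = seq.replace("AAGCTT", "AAGCTA")
    arr = list(seq)
    for start in range(period - 6, length - 5, period):
        arr[start: start + 6] = "AAGCTT"
    return "".join(arr)


@pytest.fixture(scope="session")
def genome() -> dict[str, str]:
    # cut sites every 1000 bp at k*1000 + 997
    return {
        "chr1": _chromosome_with_sites(100_000, 1000, seed=1),
        "chr2": _chromosome_with_sites(50_000, 1000, seed=2),
    }


@pytest.fixture(scope="session")
def fragmap(genome) -> FragmentMap:
    return FragmentMap.from_sequences(genome, HINDIII)


@pytest.fixture(scope="session")
def enzyme() -> Enzyme:
    return HINDIII


def _rec(header, name, flag, chrom, pos, mapq=30, read1=True):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag | (0x40 if read1 else 0x80) | 0x1
    a.reference_id = header.get_tid(chrom)
    a.reference_start = pos
    a.mapping_quality = mapq
    if not flag & 0x4:
        a.cigarstring = "50M"
    a.query_sequence = "A" * 50
    return a


def build_qc_sam(directory):
    """12 read pairs with hand-enumerated QC fates.

    Cut sites sit at k*1000 + 997 on both chromosomes.  A plus-strand read
    at reference_start p has 5' position p and looks right to the next cut
    at or after p; a minus-strand 50M read starting at r has 5' position
    r+49 and looks left.

    Fates (hand-derived below): 6 retained, 2 low-mapq/unmapped,
    1 duplicate, 1 oversized, 1 dangling end, 1 self-circle.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": "chr1", "LN": 100_000}, {"SN": "chr2", "LN": 50_000}],
    })
    recs = []

    def pair(name, chrom1, pos1, rev1, chrom2, pos2, rev2, mapq=(30, 30), flags=(0, 0)):
        recs.append(_rec(header, name, flags[0] | (0x10 if rev1 else 0), chrom1, pos1, mapq[0], True))
        recs.append(_rec(header, name, flags[1] | (0x10 if rev2 else 0), chrom2, pos2, mapq[1], False))

    # retained, inward: 5' 1950(+) d=47 to cut 1997; 5' 3050(-) d=53 to 2997;
    # size 100 <= 600; gap 1100 >= 1000
    pair("p01", "chr1", 1950, False, "chr1", 3001, True)
    # retained, outward: 5' 3050(-) d=53; 5' 29950(+) d=47; gap 26900 >= 25000
    pair("p02", "chr1", 3001, True, "chr1", 29950, False)
    # retained, same-strand (exempt from orientation filters): d=47+47, gap 1000
    pair("p03", "chr1", 4950, False, "chr1", 5950, False)
    # retained, inter-chromosomal (exempt): d=47 each
    pair("p04", "chr1", 6950, False, "chr2", 7950, False)
    # retained, inward at the exact 1 kbp boundary, both 5' ends ON cuts (size 0)
    pair("p05", "chr1", 8997, False, "chr1", 9948, True)   # 5' 8997(+) d=0; 5' 9997(-) d=0; gap 1000
    # retained, outward far apart: 5' 12050(-) d=53; 5' 45950(+) d=47; gap 33900
    pair("p06", "chr1", 12001, True, "chr1", 45950, False)
    # removed: MAPQ 5 < 10
    pair("p07", "chr1", 1950, False, "chr1", 3001, True, mapq=(5, 30))
    # removed: unmapped mate
    recs.append(_rec(header, "p08", 0, "chr1", 1950, 30, True))
    recs.append(_rec(header, "p08", 0x4, "chr1", 0, 0, False))
    # removed: duplicate flag
    pair("p09", "chr1", 1950, False, "chr1", 3001, True, flags=(0x400, 0))
    # removed: oversized, d=497+497=994 > 600 (mid-fragment reads)
    pair("p10", "chr1", 1500, False, "chr1", 20500, False)
    # removed: dangling end, inward gap 500 < 1000 (size 47+453=500 passes)
    pair("p11", "chr1", 1950, False, "chr1", 2401, True)
    # removed: self-circle, outward gap 24900 < 25000 (5' 3050(-), 27950(+))
    pair("p12", "chr1", 3001, True, "chr1", 27950, False)

    path = directory / "qc.sam"
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in recs:
            fh.write(r)
    return path


@pytest.fixture(scope="session")
def qc_sam(tmp_path_factory):
    return build_qc_sam(tmp_path_factory.mktemp("sam"))


EXPECTED_QC = {
    "total": 12, "retained": 6, "low_mapq": 2, "duplicate": 1,
    "oversized": 1, "dangling_end": 1, "self_circle": 1, "removed": 6,
}
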