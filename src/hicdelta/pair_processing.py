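"""Read-pair processing and quality control for Hi-C alignments.

Hi-C reads are frequently chimeric: sequencing runs across the proximity
ligation junction, so the 5' and 3' segments of one read come from
different loci.  Reads are split at the centre of the ligation signature
before alignment so that the 5' segment — the one that matters, since the
mate already locates the 3' partner — aligns to its true origin.

After alignment the pairs are screened for technical artifacts:
low-quality or unmapped 5' segments, PCR duplicates (flagged upstream),
implausibly large inferred sequencing fragments (non-specific cleavage),
short inward-facing pairs (dangling ends of unligated fragments) and
short outward-facing pairs (self-circularized fragments).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import h5py
import numpy as np
import pysam

from hicdelta.genome_model import FragmentMap

# orientation codes
INWARD, OUTWARD, SAME_STRAND, INTER = "inward", "outward", "same-strand", "inter-chromosomal"


def split_read_at_signature(read_sequence: str, signature: str) -> tuple[str, str | None]:
    """Split a read at the centre of the first ligation-signature occurrence.

    Returns ``(five_prime, three_prime)``; ``three_prime`` is None when the
    signature is absent.  The signature has even length by construction, so
    the centre is well defined: the 5' segment keeps the first half of the
    signature, mirroring what ligation reconstituted from its fragment end.
    """
    if not read_sequence:
        warnings.warn("empty read sequence; nothing to split")
        return "", None
    pos = read_sequence.upper().find(signature.upper())
    if pos < 0:
        return read_sequence, None
    centre = pos + len(signature) // 2
    return read_sequence[:centre], read_sequence[centre:]


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned 5' read segment."""

    chrom: str
    position: int  # 5'-most genomic position of the segment, 0-based
    strand: str  # '+' or '-'
    mapq: int = 255
    is_duplicate: bool = False


@dataclass
class PairRecord:
    """A processed Hi-C read pair with canonically ordered anchors.

    Anchors are ordered by chromosome name then position, so anchor1 is
    never downstream of anchor2 within a chromosome.
    """

    anchor1: ReadAlignment
    anchor2: ReadAlignment
    frag1: int | None = None
    frag2: int | None = None
    name: str = ""

    def __post_init__(self):
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.position) > (b.chrom, b.position):
            self.anchor1, self.anchor2 = b, a
            self.frag1, self.frag2 = self.frag2, self.frag1

    @property
    def is_intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def gap(self) -> int:
        """5'-to-5' distance between anchors (intra-chromosomal only)."""
        return self.anchor2.position - self.anchor1.position

    @property
    def orientation(self) -> str:
        if not self.is_intra:
            return INTER
        s1, s2 = self.anchor1.strand, self.anchor2.strand
        if s1 == s2:
            return SAME_STRAND
        return INWARD if s1 == "+" else OUTWARD


@dataclass
class PairFilterStats:
    """Removal tallies; causes partition the removed pairs."""

    total: int = 0
    retained: int = 0
    low_mapq: int = 0  # unmapped 5' segment or MAPQ below threshold
    duplicate: int = 0
    oversized: int = 0
    dangling_end: int = 0
    self_circle: int = 0

    @property
    def removed(self) -> int:
        return self.low_mapq + self.duplicate + self.oversized + self.dangling_end + self.self_circle

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("total", "retained", "low_mapq", "duplicate", "oversized", "dangling_end", "self_circle")}
        d["removed"] = self.removed
        return d


def _distance_to_cut(aln: ReadAlignment, fragmap: FragmentMap) -> int:
    """Distance from the read's 5' position to the nearest cut in the read direction.

    A '+' read extends rightward to the next cut at or beyond its position;
    a '-' read extends leftward.  With no cut in that direction, the
    chromosome end bounds the putative sequencing fragment.
    """
    cuts = fragmap.cuts[aln.chrom]
    length = fragmap.chrom_lengths[aln.chrom]
    if aln.strand == "+":
        i = np.searchsorted(cuts, aln.position, side="left")
        target = cuts[i] if i < len(cuts) else length
        return int(target - aln.position)
    i = np.searchsorted(cuts, aln.position, side="right") - 1
    target = cuts[i] if i >= 0 else 0
    return int(aln.position - target)


def fragment_size(pair: PairRecord, fragmap: FragmentMap) -> int:
    """Inferred sequencing-fragment size: summed read-to-cut distances.

    Each end of a ligation product terminates at a restriction cut, so the
    distance from each read's 5' position to the nearest downstream cut
    estimates that read's share of the sheared fragment.  Defined for
    inter-chromosomal pairs too, each distance on its own chromosome.
    """
    return _distance_to_cut(pair.anchor1, fragmap) + _distance_to_cut(pair.anchor2, fragmap)


@dataclass
class _Unmapped:
    """Sentinel for a template whose 5' segment(s) failed to map."""

    name: str = ""


def classify_and_filter(
    pairs: Iterable,
    fragmap: FragmentMap,
    min_mapq: int = 10,
    max_frag: int = 600,
    min_inward: int = 1000,
    min_outward: int = 25000,
) -> tuple[list[PairRecord], PairFilterStats]:
    """Apply Hi-C artifact filters in a fixed order and tally removals.

    Order: MAPQ/unmapped, duplicate flag, oversized inferred fragment
    (strictly above ``max_frag``), dangling ends (intra-chromosomal inward
    pairs closer than ``min_inward``), self-circles (intra-chromosomal
    outward pairs closer than ``min_outward``).  Inter-chromosomal and
    same-strand pairs are exempt from the orientation filters.  Each removed
    pair is charged to the first matching cause, so the tallies partition
    the removals and the filter is idempotent on its own output.
    """
    stats = PairFilterStats()
    kept: list[PairRecord] = []
    for pair in pairs:
        stats.total += 1
        if isinstance(pair, _Unmapped):
            stats.low_mapq += 1
            continue
        if min(pair.anchor1.mapq, pair.anchor2.mapq) < min_mapq:
            stats.low_mapq += 1
            continue
        if pair.anchor1.is_duplicate or pair.anchor2.is_duplicate:
            stats.duplicate += 1
            continue
        if fragment_size(pair, fragmap) > max_frag:
            stats.oversized += 1
            continue
        if pair.is_intra:
            gap = pair.gap
            if gap < 0:
                raise RuntimeError(f"negative anchor gap for {pair.name}: canonical ordering violated")
            orient = pair.orientation
            if orient == INWARD and gap < min_inward:
                stats.dangling_end += 1
                continue
            if orient == OUTWARD and gap < min_outward:
                stats.self_circle += 1
                continue
        if pair.frag1 is None:
            pair.frag1 = fragmap.fragment_index(pair.anchor1.chrom, pair.anchor1.position)
            pair.frag2 = fragmap.fragment_index(pair.anchor2.chrom, pair.anchor2.position)
        kept.append(pair)
        stats.retained += 1
    return kept, stats


def _five_prime_position(rec: pysam.AlignedSegment) -> int:
    return rec.reference_end - 1 if rec.is_reverse else rec.reference_start


def load_name_sorted_pairs(alignment_file, min_mapq: int | None = None) -> Iterator:
    """Yield one record per template from a name-sorted SAM/BAM file.

    For each template the primary alignment of each mate is taken as that
    read's 5' segment (pre-split 3' segments arrive as supplementary or
    secondary records and are ignored).  Templates whose 5' segment is
    unmapped on either side yield an ``_Unmapped`` sentinel so the QC
    stats can account for every input template.

    Raises on out-of-order input, naming the offending adjacent templates.
    """
    mode = "rb" if str(alignment_file).endswith(".bam") else "r"
    seen: set[str] = set()
    with pysam.AlignmentFile(str(alignment_file), mode, check_sq=False) as fh:
        current: str | None = None
        bucket: list[pysam.AlignedSegment] = []
        for rec in fh:
            if rec.query_name != current:
                if rec.query_name in seen:
                    raise ValueError(
                        f"input not name-sorted: template {rec.query_name!r} reappears after {current!r}"
                    )
                if current is not None:
                    yield _template_to_pair(current, bucket)
                    seen.add(current)
                current, bucket = rec.query_name, []
            bucket.append(rec)
        if current is not None:
            yield _template_to_pair(current, bucket)


def _template_to_pair(name: str, records: list[pysam.AlignedSegment]):
    def pick(first: bool):
        for rec in records:
            if rec.is_read1 != first:
                continue
            if rec.is_supplementary or rec.is_secondary:
                continue  # 3' segment of a pre-split chimeric read
            if rec.is_unmapped:
                return None
            return ReadAlignment(
                chrom=rec.reference_name,
                position=_five_prime_position(rec),
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                is_duplicate=rec.is_duplicate,
            )
        return None

    a1, a2 = pick(True), pick(False)
    if a1 is None or a2 is None:
        return _Unmapped(name=name)
    return PairRecord(anchor1=a1, anchor2=a2, name=name)


_ORIENT_CODE = {INWARD: 0, OUTWARD: 1, SAME_STRAND: 2, INTER: 3}
_ORIENT_NAME = {v: k for k, v in _ORIENT_CODE.items()}


class PairStore:
    """HDF5-backed store of retained pairs, one table per chromosome pair.

    Group names are ``"chromA|chromB"`` with chromA <= chromB; columns are
    pos1, pos2, frag1, frag2, orientation (coded).  Technical replicates
    are pooled by writing several pair lists into one store.
    """

    def __init__(self, path):
        self.path = str(path)

    def write(self, pairs: Iterable[PairRecord], stats: PairFilterStats | None = None, mode="w") -> None:
        tables: dict[tuple[str, str], list] = {}
        for p in pairs:
            key = (p.anchor1.chrom, p.anchor2.chrom)
            tables.setdefault(key, []).append(
                (p.anchor1.position, p.anchor2.position, p.frag1 if p.frag1 is not None else -1,
                 p.frag2 if p.frag2 is not None else -1, _ORIENT_CODE[p.orientation])
            )
        with h5py.File(self.path, mode) as fh:
            for (c1, c2), rows in tables.items():
                arr = np.asarray(rows, dtype=np.int64)
                name = f"{c1}|{c2}"
                if name in fh:  # pooling technical replicates
                    old = fh[name][...]
                    del fh[name]
                    arr = np.vstack([old, arr])
                fh.create_dataset(name, data=arr)
            if stats is not None:
                fh.attrs["qc_stats"] = json.dumps(stats.as_dict())

    def chrom_pairs(self) -> list[tuple[str, str]]:
        with h5py.File(self.path, "r") as fh:
            return [tuple(k.split("|")) for k in fh.keys()]

    def read(self, chrom1: str, chrom2: str) -> np.ndarray:
        with h5py.File(self.path, "r") as fh:
            return fh[f"{chrom1}|{chrom2}"][...]

    def iter_pairs(self) -> Iterator[tuple[str, str, np.ndarray]]:
        with h5py.File(self.path, "r") as fh:
            for key in fh.keys():
                c1, c2 = key.split("|")
                yield c1, c2, fh[key][...]

    def qc_stats(self) -> dict | None:
        with h5py.File(self.path, "r") as fh:
            raw = fh.attrs.get("qc_stats")
        return json.loads(raw) if raw else None
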