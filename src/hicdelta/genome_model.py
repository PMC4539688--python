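"""Restriction-digest model of a genome.

A Hi-C experiment begins with a restriction digest, so the genome is
naturally discretized into restriction fragments.  This module models the
enzyme (recognition site and cut offset), digests chromosome sequences
into ordered cut positions, derives the ligation signature created by
blunt-end ligation of filled-in overhangs, and builds fixed-width bins
whose boundaries are rounded to the nearest restriction site — the true
limit of spatial resolution in Hi-C.

Coordinates are 0-based half-open throughout the library; user-facing
reports convert to 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A palindromic restriction enzyme leaving a 5' overhang or blunt end.

    Parameters
    ----------
    recognition : str
        Recognition sequence, uppercase A/C/G/T (e.g. ``"AAGCTT"`` for HindIII).
    cut_offset : int
        Distance in nt from the 5' end of the site to the top-strand cut.
        HindIII (A^AGCTT) has ``cut_offset=1``.

    The overhang length is ``len(recognition) - 2 * cut_offset``; 3'-overhang
    cutters (negative overhang) are rejected because their junctions are not
    regenerated by fill-in ligation.
    """

    recognition: str
    cut_offset: int

    def __post_init__(self):
        site = self.recognition.upper()
        object.__setattr__(self, "recognition", site)
        if not site or not set(site) <= set("ACGT"):
            raise ValueError(f"recognition sequence must be non-empty A/C/G/T: {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"cut offset {self.cut_offset} outside recognition site of length {len(site)}")
        if reverse_complement(site) != site:
            raise ValueError(f"recognition site {site!r} is not palindromic")
        if self.overhang < 0:
            raise ValueError(
                f"{site!r} with cut offset {self.cut_offset} leaves a 3' overhang; only 5' overhangs or blunt cutters are supported"
            )

    @property
    def overhang(self) -> int:
        return len(self.recognition) - 2 * self.cut_offset

    @classmethod
    def from_string(cls, text: str) -> "Enzyme":
        """Parse an ``"SEQ:offset"`` config string, e.g. ``"AAGCTT:1"``."""
        try:
            seq, off = text.split(":")
            return cls(seq.strip(), int(off))
        except ValueError as exc:
            raise ValueError(f"enzyme must be given as 'SEQ:offset', got {text!r}") from exc


def ligation_signature(enzyme: Enzyme) -> str:
    """Sequence created at a proximity-ligation junction after fill-in.

    Both fragment ends retain the site prefix up to the cut plus the
    filled-in overhang; blunt ligation joins them, giving
    ``recognition[:p + L] + recognition[p:]`` of length ``len(site) + L``
    where ``p`` is the cut offset and ``L`` the overhang.  For HindIII
    (AAGCTT, p=1) this is AAGCTAGCTT.
    """
    p, site = enzyme.cut_offset, enzyme.recognition
    return site[: p + enzyme.overhang] + site[p:]


def digest(chrom_sequence: str, enzyme: Enzyme) -> np.ndarray:
    """Ordered cut positions for one chromosome sequence.

    One cut per exact occurrence of the recognition site (overlapping
    occurrences all count), placed at the centre of the occurrence —
    the blunt position after fill-in.  Occurrences containing N are
    skipped.  Returns a sorted int array, possibly empty.
    """
    seq = chrom_sequence.upper()
    site = enzyme.recognition
    half = len(site) // 2
    # lookahead so overlapping occurrences are all found
    cuts = [m.start() + half for m in re.finditer(f"(?={site})", seq)]
    return np.asarray(cuts, dtype=np.int64)


@dataclass
class FragmentMap:
    """Per-chromosome cut positions and the restriction fragments they imply.

    ``cuts[chrom]`` is a strictly increasing int array of interior cut
    positions in ``(0, length)``; fragments are the half-open intervals
    between consecutive boundaries ``0, cuts..., length`` and tile the
    chromosome exactly.
    """

    chrom_lengths: dict[str, int]
    cuts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            c = np.asarray(self.cuts.get(chrom, []), dtype=np.int64)
            if c.size and (np.any(np.diff(c) <= 0) or c[0] < 0 or c[-1] > length):
                raise ValueError(f"cut positions on {chrom} must be strictly increasing within [0, {length}]")
            # cuts at 0 or length are boundaries already, not interior cuts
            self.cuts[chrom] = c[(c > 0) & (c < length)]

    @classmethod
    def from_sequences(cls, sequences: dict[str, str], enzyme: Enzyme) -> "FragmentMap":
        return cls(
            chrom_lengths={c: len(s) for c, s in sequences.items()},
            cuts={c: digest(s, enzyme) for c, s in sequences.items()},
        )

    @classmethod
    def from_fasta(cls, path, enzyme: Enzyme) -> "FragmentMap":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no FASTA records in {path}")
        return cls.from_sequences(seqs, enzyme)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def boundaries(self, chrom: str) -> np.ndarray:
        """All fragment boundaries on a chromosome, including 0 and the end."""
        return np.concatenate(([0], self.cuts[chrom], [self.chrom_lengths[chrom]]))

    def fragments(self, chrom: str) -> np.ndarray:
        """(n_frag, 2) half-open fragment intervals tiling the chromosome."""
        b = self.boundaries(chrom)
        return np.column_stack((b[:-1], b[1:]))

    def fragment_index(self, chrom: str, position: int) -> int:
        """Index of the fragment containing ``position`` (half-open)."""
        length = self.chrom_lengths[chrom]
        if not 0 <= position < length:
            raise ValueError(f"position {position} outside {chrom} of length {length}")
        return int(np.searchsorted(self.cuts[chrom], position, side="right"))


@dataclass
class BinMap:
    """Fixed-width genomic bins with boundaries snapped to restriction sites.

    ``boundaries[chrom]`` is the ordered boundary vector (first 0, last the
    chromosome length); bin ``k`` of a chromosome is
    ``[boundaries[k], boundaries[k+1])``.  ``offsets`` maps a chromosome
    to the global index of its first bin, so bins have a single genome-wide
    numbering.
    """

    width: int
    boundaries: dict[str, np.ndarray]

    def __post_init__(self):
        self.offsets: dict[str, int] = {}
        total = 0
        for chrom, b in self.boundaries.items():
            if len(b) < 2 or np.any(np.diff(b) <= 0):
                raise ValueError(f"degenerate bin boundaries on {chrom}")
            self.offsets[chrom] = total
            total += len(b) - 1
        self.n_bins = total

    @property
    def chromosomes(self) -> list[str]:
        return list(self.boundaries)

    def n_bins_of(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    def bin_of(self, chrom: str, position: int) -> int:
        """Within-chromosome bin index of a position (half-open convention)."""
        b = self.boundaries[chrom]
        if not b[0] <= position < b[-1]:
            raise ValueError(f"position {position} outside binned range of {chrom}")
        return int(np.searchsorted(b, position, side="right") - 1)

    def bin_interval(self, chrom: str, index: int) -> tuple[int, int]:
        b = self.boundaries[chrom]
        return int(b[index]), int(b[index + 1])

    def midpoint(self, chrom: str, index: int) -> float:
        s, e = self.bin_interval(chrom, index)
        return (s + e) / 2.0

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, b in self.boundaries.items():
                for k in range(len(b) - 1):
                    fh.write(f"{chrom}\t{b[k]}\t{b[k + 1]}\tbin_{self.offsets[chrom] + k}\n")


def build_bins(fragmap: FragmentMap, width: int) -> BinMap:
    """Partition each chromosome into ~``width`` bp bins ending on cut sites.

    Nominal boundaries sit at multiples of ``width``; each interior boundary
    is moved to the nearest restriction cut (ties broken toward the larger
    coordinate).  Chromosome start and end are always boundaries.  Nominal
    boundaries that collapse onto the same cut after rounding are
    deduplicated, dropping the empty bin.
    """
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    boundaries = {}
    for chrom, length in fragmap.chrom_lengths.items():
        cuts = fragmap.cuts[chrom]
        nominal = np.arange(width, length, width, dtype=np.int64)
        if cuts.size == 0 or nominal.size == 0:
            boundaries[chrom] = np.array([0, length], dtype=np.int64)
            continue
        # nearest cut; on ties prefer the larger cut
        idx = np.searchsorted(cuts, nominal)
        lo = np.clip(idx - 1, 0, len(cuts) - 1)
        hi = np.clip(idx, 0, len(cuts) - 1)
        pick = np.where(nominal - cuts[lo] < cuts[hi] - nominal, cuts[lo], cuts[hi])
        b = np.unique(np.concatenate(([0], pick, [length])))
        boundaries[chrom] = b
    return BinMap(width=width, boundaries=boundaries)
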