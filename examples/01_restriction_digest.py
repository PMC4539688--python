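"""Restriction digestion, ligation signatures and site-rounded bins.

Builds a toy chromosome, digests it with HindIII, derives the ligation
signature created at proximity-ligation junctions, and partitions the
chromosome into bins whose boundaries snap to restriction sites.
"""

import numpy as np

from hicdelta import Enzyme, FragmentMap, build_bins, ligation_signature
from hicdelta.genome_model import digest

hindiii = Enzyme("AAGCTT", 1)
print(f"HindIII: site {hindiii.recognition}, cut offset {hindiii.cut_offset}, "
      f"5' overhang {hindiii.overhang} nt")
print(f"ligation signature: {ligation_signature(hindiii)}")
# The signature is what fill-in + blunt ligation writes across a junction;
# reads are split at its centre before alignment.

rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), size=5000))
seq = seq[:800] + "AAGCTT" + seq[806:2500] + "AAGCTT" + seq[2506:4200] + "AAGCTT" + seq[4206:]

cuts = digest(seq, hindiii)
print(f"\ncut positions (site centres): {cuts.tolist()}")

fragmap = FragmentMap(chrom_lengths={"chr_toy": len(seq)}, cuts={"chr_toy": cuts})
print(f"restriction fragments: {fragmap.fragments('chr_toy').tolist()}")

binmap = build_bins(fragmap, width=1500)
print(f"\n1.5 kbp bins, boundaries rounded to the nearest cut: "
      f"{binmap.boundaries['chr_toy'].tolist()}")
# Interior boundaries coincide with cut positions: spatial resolution in
# Hi-C is limited by the digest, so bin edges between cut sites would be
# artificial precision.
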