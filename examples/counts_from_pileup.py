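"""Derive allele counts from a samtools text pileup restricted to a panel.

Builds a tiny pileup by hand (two SNP sites plus one off-panel site) and
tallies base calls with the default Q20 quality filter; low-quality calls
are discarded before the major/minor alleles are chosen.
"""

import tempfile
from pathlib import Path

from fetalfrac import SnpPanel, counts_from_pileup

tmp = Path(tempfile.mkdtemp())
pileup = tmp / "sample.pileup"
# columns: chrom, 1-based pos, ref, depth, read bases, base qualities
pileup.write_text(
    "chr1\t101\tA\t10\t.........G\tIIIIIIIIII\n"  # 9 ref A + 1 alt G, all Q40
    "chr1\t205\tC\t6\t..TT..\tII++II\n"           # the two T calls are Q10
    "chr1\t900\tG\t4\t....\tIIII\n"               # not in the panel
)
panel_bed = tmp / "panel.bed"
panel_bed.write_text("chr1\t100\t101\nchr1\t204\t205\n")  # BED is 0-based

records = counts_from_pileup(pileup, SnpPanel.from_bed(panel_bed), min_base_quality=20)
for r in records:
    print(f"{r.chrom}:{r.pos}  major={r.major_base} x={r.x}  minor={r.minor_base} y={r.y}")
# Site 101 keeps a true minor allele (G); at site 205 the T calls fall below
# Q20 and are discarded, so no minor allele survives.
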