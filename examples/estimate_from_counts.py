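"""Estimate the fetal fraction of one plasma sample from SNP allele counts.

Simulates a targeted-sequencing sample (150-fold depth, true fetal fraction
15%), writes it as the counts TSV the estimator consumes, and runs the full
pipeline: sample depth, targeted-zone filtering, per-locus f = 2y/(x+y),
median aggregation.
"""

import tempfile
from pathlib import Path

from fetalfrac import (
    SimulationParams,
    estimate_fetal_fraction,
    read_counts_table,
    simulate_dataset,
    write_counts_table,
)

ds = simulate_dataset(SimulationParams(D=150, f=0.15, seed=42))
path = Path(tempfile.mkdtemp()) / "plasma_counts.tsv"
write_counts_table(ds.loci, path)

loci = read_counts_table(path)
est = estimate_fetal_fraction(loci)

print(f"sample depth          : {est.D:.0f}-fold")
print(f"effective SNPs in zone: {est.n_effective}")
print(f"estimated f           : {est.f_raw:.4f} ({100 * est.f_raw:.2f}%)")
print(f"correction applied    : {est.corrected}")
# The estimate is the median per-locus fraction over loci where the mother is
# homozygous and the fetus heterozygous; at this depth and fraction no
# depth-bias correction is needed and the raw value is within ~1% of truth.
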