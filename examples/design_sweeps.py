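"""Study-design sweeps: how much depth, and how many SNPs, are enough?

Runs reduced-grid versions of the two sweeps: mean absolute deviation e1
versus sequencing depth at a fixed 3.5% fetal fraction, and mean relative
deviation e2 (plus the targeted-zone census) versus the number of
predefined SNP loci at 65-fold depth.
"""

import warnings

from fetalfrac import build_correction_model, min_depth_sweep, min_snps_sweep

# calibration cells with an empty targeted zone are dropped with a warning;
# that is routine at very low fraction x depth, so keep the output clean
warnings.simplefilter("ignore", UserWarning)

depths = [70, 100, 150, 200]
model = build_correction_model(depths=depths + [65], seed=11)

out = min_depth_sweep(
    f=0.035, n_loci=11_000, depths=depths, n_reps=10, seed=3, model=model
)
print("depth sweep at f = 3.5% (11,000 loci):")
for p in out.sweep.points:
    print(f"  {p.value:>5.0f}-fold  mean e1 = {p.mean_deviation:.2f} pct points")
print(f"  minimal depth with mean e1 < 1 point: {out.min_depth:.0f}-fold")

snp = min_snps_sweep(
    f=0.056, D=65, loci_counts=[500, 1000, 2000, 4000], n_reps=10, seed=3, model=model
)
print("SNP-count sweep at f = 5.6%, 65-fold:")
for p in snp.sweep.points:
    print(
        f"  {p.value:>6.0f} loci  mean e2 = {p.mean_deviation:.3f}"
        f"  zone census = {p.mean_zone_loci:.0f}"
    )
print(f"  minimal count with a reliably populated zone (>30): {snp.min_loci_zone}")
# Accuracy improves with depth and with the number of predefined loci; the
# zone census is the driver — estimates resting on more than ~30 zone loci
# are stable.
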