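# Methods

## Model and assumptions

A maternal-plasma sample is a mixture of maternal (fraction 1−f) and fetal
(fraction f) cell-free DNA. At a biallelic SNP the maternal/fetal genotype
combination takes one of four forms — AAaa, AAab, ABaa, ABab (upper case
maternal, lower case fetal) — with expected minor-allele fractions at total
depth n = x+y of

| category | expected minor fraction | role |
|---|---|---|
| AAaa | e (sequencing error) | noise floor |
| AAab | f/2 | signal carrier |
| ABaa | (1−f)/2 | excluded by geometry |
| ABab | 1/2 | excluded by geometry |

Allele counts are treated as normally distributed with variance equal to
the mean (the normal limit of Poisson-dispersed counts), and per-locus
total depth as Poisson around the sample depth D. Under these assumptions
the four categories occupy distinct regions of the (x, y) plane and the
AAab region — the *targeted zone* — can be cut out with three inequalities
without calling any genotype:

1. **ratio line** `y ≤ x/3`: equivalent to f ≤ 1/2, the physiological
   ceiling; removes ABaa/ABab, whose minor fraction is ≥ 1/4.
2. **error line** `y > n·e + k_error·√(e·n)`: the maximum minor count
   attributable to base-call error, mean plus k standard deviations of a
   Poisson(e·n). `e = 0.01` by default (post-Q20 residual error).
3. **depth window** `|n − D| ≤ 3·√D`: discards loci whose coverage is
   atypical of the sample (D = median of n over all loci).

Each zone locus contributes f̂ᵢ = 2y/n; the sample estimate is the median
of these. The ratio line guarantees every accepted f̂ᵢ ≤ 0.5.

Boundary conventions: the error line is strict (a locus exactly at the
error ceiling is indistinguishable from error), the ratio line and depth
window are inclusive. Ties between equally frequent bases are broken
lexicographically (A<C<G<T); f is unaffected because it uses x+y and 2y
only. All medians use the mean-of-central-pair convention for even
lengths. When no second allele is observed the minor base is recorded as
`"."`.

**Low-depth relaxation.** Below 100-fold sample depth, `k_error` drops
from 3 to 2 (≈95% rather than ≈99.7% one-sided error coverage): with few
reads per locus the 3σ ceiling would swallow most genuine fetal minor
alleles. The depth window stays at 3·√D throughout.

## Depth-bias correction

When D < 100-fold or the raw estimate is below 10%, the error line
truncates the AAab minor-count distribution from below: only upper-tail
loci survive, and the zone median converges to a depth-dependent floor
near 2·⌈n·e + k√(e·n)⌉/D rather than to f. The bias is systematic at a
given depth, so it is removed by calibration:

- for each calibration depth, simulate datasets over a grid of true
  fractions (0.5%–25% in 0.5% steps, 25 replicates per cell, generator
  defaults), score each with the uncorrected estimator, and regress the
  standard (label-aware) fraction on the raw estimate by ordinary least
  squares;
- at application time the entry nearest in depth (ties to the lower depth)
  is evaluated at the sample's raw estimate, clipped to the calibrated raw
  range, and clamped to [0, 0.5].

**Why a polynomial and not a straight line.** The calibration relation is
a smooth hockey-stick: the local slope of standard-on-raw is ≈2–3 near the
low-fraction floor and ≈1 above ~10%. A single affine fit per depth leaves
1.4–4.8 percentage points of residual bias at f = 3.5% (measured at
depths 65–200 on the calibration grid itself) and distorts the
well-behaved upper branch (fitted slope ≈1.2 at 150-fold where the
estimator is essentially unbiased). Each depth's curve is therefore a
low-order polynomial — cubic by default, configurable down to degree 1
(which recovers the affine form) — the minimal flexible form that maps
both the floor and the identity branch onto the truth scale; with it the
residual bias at f = 3.5% is 0.2–0.7 points at every depth from 70- to
200-fold. Extrapolation outside the calibrated raw range is avoided by
clipping, which also keeps the polynomial tails harmless. Cells of the
calibration grid in which every replicate leaves the zone empty are
treated as missing and dropped (never as zero); a depth with fewer than 5
usable cells is refused.

Correction triggers exactly when the direct regime does not hold
(D < 100-fold or raw f < 10%). If a correction is indicated but no model
is supplied, the raw estimate is returned with a warning.

## Synthetic-data generator

The generator draws, per locus, a category from proportions
(0.7, 0.1, 0.1, 0.1) for (AAaa, AAab, ABaa, ABab), then minor/major counts
from normals with variance equal to the mean, rounded and truncated at
zero, and reordered so x ≥ y. Minor-count means are e_sim·D, (f/2)·D,
((1−f)/2)·D and D/2 respectively, with majors at D minus the minor mean.
Two error rates deliberately coexist: `e_sim = 0.0026` (the platform
base-call rate driving AAaa minor counts in simulation) and `e = 0.01`
(the post-Q20 bound used by the zone's error line); they are never
conflated. Per-locus totals are not separately Poisson-resampled — the
mean-variance-equal normals on each allele already disperse them.

The dataset's **standard f** is the median of 2y/n over the loci whose
*true* label is AAab: what a perfect genotype oracle would report. All
simulation accuracy metrics compare against this standard value, not
against the parameter f, because at low f·D the AAab minor counts are
small integers and their median fraction sits visibly below f (e.g.
standard ≈ 0.029–0.031 at f = 0.035, D = 70): the discretisation affects
reference and estimator alike.

What the generator does *not* emulate: linked reads and haplotype
structure, GC and amplification bias, alignment error, non-biallelic
sites, the CpG-skewed SNP spectrum, and position-dependent base-call
error. Passing tests therefore demonstrate the statistical machinery —
zone geometry, median aggregation, calibration — under the stated
dispersion model, not robustness to every artefact of real plasma
sequencing.

## Deviation metrics and design sweeps

Accuracy is scored by the absolute deviation e1 = |standard − deduced| in
percentage points and the relative deviation e2 = |standard −
deduced|/standard. Zone quality is summarised as sensitivity (% of true
AAab loci captured) and specificity (% of non-AAab loci excluded) —
the standard confusion-matrix reading with AAab as the positive class.

Two sweeps answer design questions with seeded replicates (default 20 per
point, means reported):

- **minimum depth**: at f = 3.5% with 11,000 predefined loci, mean e1 per
  depth with the corrected estimator; the minimal depth is the smallest
  with mean e1 < 1 point.
- **minimum SNP count**: at 65-fold and fixed f, mean e2 and the mean
  targeted-zone census per predefined locus count. Two minimal-count
  readings are reported side by side: the smallest count with mean
  e2 < 1%, and the smallest count whose zone reliably holds more than 30
  loci. Under this generator the e2 < 1% reading is never reached at
  65-fold even with 11,000 loci — at f = 5% the corrected estimator's
  ~0.9-point absolute error is already ~18% in relative terms — so the
  zone-census reading (met at 1000–2000 loci for f ≥ 5.6%) is the
  operative one; the absolute-deviation counterpart of the same estimates
  stays below 1 point.

The acceptance script uses a 70–200-fold depth grid in steps of 10 with 20
replicates per point and calibration at the same depths on an independent
seed stream; the test suite uses a 5-depth subset. These problem sizes
give replicate standard errors comfortably below the thresholds being
checked.

## Clinical cohort fixture

The package ships, as a TSV fixture, the published per-sample table of an
18-pregnancy targeted-sequencing cohort (depth, zone sensitivity/
specificity, standard, estimated and — below 100-fold — corrected
fractions, in percent, at the source's print precision). The summary
reproduces its headline medians: pre-correction deviation 1.8 points
(range 0.6–3.6) and post-correction 0.65 (0.2–2.1) over the eight
low-depth samples, median depth 125-fold, and a median final deviation of
0.35 → 0.4 at one decimal (rounded half-up). Per-row deviations are
rounded to 4 decimals before aggregation so that binary floating point
does not perturb medians of one-decimal inputs. The overall median is also
reported in a relative reading (100·|dev|/standard) for comparison; the
absolute reading is the one consistent with the cohort's published
summary.

## chrY cross-estimator

For a male fetus, chrY is present at f/2 haploid copies per diploid
genome, so f = 2·median(chrY site depth)/median(autosomal site depth),
clamped to [0, 1]. It is exposed as an independent cross-check (it needs
no SNP counts) and recovers f within ±0.01 on Poisson-coverage
simulations at 200-fold.

## Known limitations

- **Direct-regime corner bias.** The no-correction rule (D ≥ 100-fold and
  raw f ≥ 10%) is slightly optimistic at its own corner: at (D ≈ 100–130,
  f ≈ 10–12%) the error-line floor sits at or just below f, truncation
  bias of ~1.2 points persists, and the trigger does not fire because the
  raw value exceeds 10%. Strictly inside the region the raw estimator is
  accurate to < 1 point.
- **Discretisation at low f·D.** Below roughly f·D ≈ 3 the informative
  minor counts are single-digit integers; both the standard value and the
  estimate move in visible steps, and relative deviations at f ≤ 5% are
  dominated by this granularity rather than by sampling noise.
- **Correction validity is conditional on the generator.** The calibration
  curves are only as good as the dispersion model behind them; real-data
  depth profiles with overdispersion beyond Poisson would need
  recalibration against matched simulations or mixed real reads.
- No read de-duplication is performed before pileup tallying, and the
  pileup path trusts the aligner's base alignments (no realignment).
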