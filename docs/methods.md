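# Methods

This note documents the models implemented in fragsig, the defaults and
why they hold, what the synthetic data does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Coverage-dip quantification at region sets

### Signal model

Tumor-specific open chromatin is nucleosome-depleted in tumor cells, so
the cfDNA fragments a tumor sheds under-cover those regions. Aggregating
fragment coverage over a catalog of such regions and comparing a sample
to healthy controls turns this depletion into a quantitative
tumor-content signal that needs no somatic mutation.

Coverage is computed fragment-wide (every base under a fragment counts),
restricted to fragments with mapping quality ≥ 20, and scaled to a
genome-wide mean of 1. Each region is split into five core bins of 10,
15, 50, 15 and 10 % of its length — so regions of different sizes align
by ordinal bin — plus 20 kb of 500 bp bins on each side. Core widths use
largest-remainder rounding, which is exact for lengths divisible by 20
and keeps the widths summing to the region length otherwise. Per-bin
coverage is divided by the 500 kb copy-ratio window value from an
upstream CNA caller, so copy-number structure does not masquerade as
chromatin signal; bins in missing, non-positive or filtered windows are
excluded.

### Fragment-level bias model

Sequencing and library biases act on whole fragments, so a bin's coverage
depends on sequence content well beyond its own borders. The *coverage
weight vector* captures this: for fragment lengths drawn from the
sample's own length distribution (200 draws by default; a deterministic
expectation mode weights each length by its probability and is used for
exact tests), a fragment of length L starting at every position p in
[−L, bin+L) contributes the fraction of bin bases it overlaps to every
position it covers. The result is a per-offset influence profile,
independent of genomic content, computed once per (sample, bin width).

Per bin, 46 predictors are derived under this weighting, all in [0, 1]:

- 1 GC factor (per-position weights: A/T = 0, G/C = 1, N = 0.461, the
  genome-wide mean GC);
- 10 dinucleotide + 32 trinucleotide factors (reverse-complement pairs
  share a factor; the k-mer starting at each position scores 1);
- 3 mappability factors from a 75 bp-read mappability track: forward
  (read starting at p), reverse (forward mappability of p − 75), and the
  per-position maximum. Endpoint variants of the weight vector — the
  influence assigned only to the fragment start (forward) or end
  (reverse) — weight the first two; the maximum uses their mean, a
  choice made here because only the variable, not its weighting, is
  pinned down by the method description.

A random forest (50 trees, per-split feature subsampling p/3) regresses
coverage on these factors using **flank bins only** — excluding the five
core bins means a genuine central dip cannot be learned away as bias —
and its prediction is subtracted from every bin. Corrected values are
averaged across regions into one profile per sample.

### Dip model and metrics

The profile y(x) (x = bp from region midpoint) is fit by damped least
squares (Levenberg–Marquardt via lmfit, bounds enforced by parameter
transformation) as an intercept plus three Gaussians centered at x = 0,
with σ boxes reflecting three regulatory scales: 20–200 bp
(transcription-factor footprints), 200–3000 bp (enhancers/promoters),
3000–40000 bp (super-enhancer-scale domains). After a first pass over
all samples, each σ is fixed at its across-sample median and amplitudes
and intercept are refit, which stabilizes per-sample metrics.
Initialization: intercept at the profile median, amplitudes at a third of
the center-minus-median deficit, σ at the geometric middle of each box.
A non-converged fit is flagged and reported, never silently replaced.

Metrics: AOC (trapezoid area between the intercept and the fitted curve
over the binned domain; the analytic −ΣAᵢσᵢ√2π is reported alongside and
agrees within ~2 % — the difference is finite-domain truncation of the
widest component), AOC excluding x ∈ [−σ₁, σ₁], the summed fitted values,
per-component amplitudes, intercept, and total dip depth −(A₁+A₂+A₃).
Signs are chosen so depletion is positive; the method description leaves
the convention open, and a "larger = more tumor signal" orientation reads
naturally. Detection compares a sample's metric to healthy controls:
z = (x − mean)/sd with the sample standard deviation, leave-one-out when
scoring a control, and a strict |z| > 3 flag. AOC is the default metric
for broad tumor-specific region sets; total dip depth suits the sharp
dips at ubiquitously open sites.

## Fragment-size analytics

Length histograms are kept on a 20–800 bp support. Global features:
range proportions P(100–150), P(160–180), P(180–220), P(250–320), the
ratios P(100–150)/P(163–169) and P(160–180)/P(180–220), and the 10 bp
oscillation amplitude — the mean histogram value at the fixed local
maxima (81, 92, 102, 112, 122, 134, 144 bp) minus the mean at the minima
(84, 96, 106, 116, 126, 137, 148 bp). In-silico size selection keeps
fragments in the closed interval 90–150 bp, enriching tumor-derived DNA.

Regional analysis counts short (100–150 bp) and long (151–220 bp)
fragments per 100 kb tile, assigning each fragment to the tile containing
its midpoint (a fragment is never double-counted; the assignment rule is
a documented choice, as "mapping to the bin" admits several readings).
Tiles overlapping a blacklist or assembly-gap interval, or with fewer
than 500 fragments (a configurable floor; the expected count at study
depth is ~25,000, so this only removes pathological tiles), are excluded.
Counts are GC-corrected by LOWESS (frac = 0.75) separately per size
class — corrected = count − fit(gc) + mean(count), recentering so the
correction removes the trend without changing the scale — then
log₂(S/L) is taken, each sample is centered on its CNA-neutral tiles,
and per-tile z-scores against the control distribution get two-sided
normal p-values with Benjamini–Hochberg FDR at 0.05. Chromosome-arm
summaries average log₂(S/L) per arm and z-score the averages; an arm is
CNA-affected if any of its tiles is non-neutral. Read-depth features use
5 Mb tiles: LOESS GC correction per size class, within-sample z-transform
of the 100–220 bp counts (plus a 100–150 bp-only variant), and per-arm
mean depths normalized to sum 1.

## Fusion-breakpoint tumor content

Reads re-mapped to an augmented reference (fusion allele plus both
germline partner loci) support an allele only if they span the junction,
the microhomology window, and at least one distinguishing base on each
side: with junction j and microhomology m, start ≤ j−1 and end ≥ j+m+1.
For a heterozygous fusion, tumor content is 2f/((g₁+g₂)/2 + f); the two
germline counts are averaged to damp local coverage fluctuations.
Multiple breakpoints are averaged, then the estimate is clamped to
[0, 1] (sampling noise can push the raw ratio above 1; clamping after
averaging preserves information from individually noisy breakpoints).
The consensus over evidence sources is the mean of the available
estimates, with positive fusion evidence forcing a nonzero consensus —
the combination rule is deliberately isolated in one function because no
single rule is canonical.

## Classification harness

Evaluation draws n patients with replacement per iteration (default
100 iterations); samples of drawn patients train, the rest test, and
iterations with fewer than 5 test samples of either class are redrawn.
All of a patient's samples stay on one side of the split. Inner
stratified 5-fold CV (shared folds across candidates) selects among:
linear SVM (C ∈ 2^{−5,−3,−1,1,3,7,9,11,13,15}), elastic-net logistic GLM
(l1 ratio ∈ {0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1}), random forest
(200 trees), and an optional 2×200 rectifier network with adaptive
learning rate (off by default purely for runtime). For all but the SVM
the minority class is oversampled by ⌈majority/minority⌉ duplication
inside each training fold (never across fold boundaries). Selection is by
mean inner AUC; ties go to the simpler family (GLM < SVM < RF < NN).
Linear models sit behind a standardizer; margin classifiers emit
sigmoid-linked decision values as probabilities (monotone, so
ROC-identical; meta-learner inputs only need a consistent monotone
scale). The meta-learner is an ordinary-least-squares (Gaussian) linear
model over per-feature-set probabilities, trained on out-of-fold
training-set predictions only. ROC curves are averaged vertically on a
fixed 1001-point FPR grid with (0,0) and (1,1) pinned; the aggregate AUC
is the trapezoid under the mean curve. Multi-source cohorts are
harmonized by standardizing each feature per source on that source's
healthy controls; features with zero control spread are dropped.

A caution this harness makes reproducible: normalizing a *complete*
dataset before splitting makes the two classes' means equal by
construction, so random train-set differences reappear mirrored in the
test set and a classifier trained to separate two identically distributed
sources scores systematically *below* 0.5 — the validation study
demonstrates this on all-control sources.

## Synthetic data: what it emulates, and what it does not

One simulated chromosome (default 2.5 Mb) carries 40 regions of 1 kb
standing in for a tumor-specific open-chromatin catalog. The GC landscape
is a sum of smooth sinusoids (periods 11–149 kb, ±5 %) around a mean of
0.42, plus a +10 % GC bump (σ = 2 kb) at every region — regulatory
regions are genuinely GC-rich, and this bump is what makes the GC bias a
*confound* of the dip signal rather than independent noise, which is
exactly the situation the bias model exists for. Mappability is 1 except
for 30 patches of 0.4. Fragment lengths are discretized skew-normals with
the mode pinned (healthy 167 bp / spread 28, tumor 145 bp / spread 32,
matching the shorter tumor-fragment phenotype); sampling acceptance is
thinned by a logistic in fragment GC (slope 8), by the mappability at the
fragment start, and — for tumor fragments near region midpoints — by a
sum of centered Gaussians (amplitudes 0.25/0.35/0.3, σ 150/1200/6000 bp,
chosen so the titration separates decisively from the control spread
after the bias model absorbs the share of the dip that co-varies with
the GC bump,
within the fitter's σ boxes so recovery is well-posed; a hard-mask mode
exists for misspecification tests). Depth is 12× fragment coverage,
matching deep cfDNA WGS; cohorts default to 20–22 controls, the size of a
typical healthy-donor arm. Sampling proceeds until the target fragment
count is reached, so biases shape *where* fragments fall, not how many
there are. Per-sample seeds spawn from one master seed.

Not emulated: read-level errors and alignment (fragments are exact
intervals), duplicate fragments, chromosome structure beyond one
chromosome, inter-individual variation in region activity, batch effects
within a source, and CNAs (copy-ratio input is exercised with neutral and
constructed tables instead). Passing validation therefore shows the
*methods* behave as designed under their own generative assumptions —
bias removal, calibration, power, determinism — not that real-plasma
performance figures transfer.

## Validation studies and problem sizes

The studies in `fragsig.studies` (run by the test suite and
`scripts/acceptance.py`) use: exhaustive weight-vector enumeration for
all fragment lengths ≤ 5 and bin sizes ≤ 5; an analytic single-Gaussian
profile (A = 0.2, σ = 1000) for closed-form recovery; one shared cohort
of 20 controls plus 20 cases at each tumor fraction in
{0, 0.05, 0.2, 0.5, 0.95} for null flatness and titration; 10,000
100 kb tiles, 22 controls and a +5σ shift in 1 % of tiles for S/L
calibration and power (the shift is injected on the noise-free expected
value, isolating the detection step: with the case's own per-tile noise
included, the noncentral-t power of a 5σ effect at ~21 control degrees of
freedom is mathematically ~0.90, regardless of implementation); spiked
fusion mixtures at 4000-fragment depth; separable / shuffled cohorts of
60 samples (30 bootstrap iterations) and a 24+22 two-source null
(100 iterations) for the harness; and a 600 kb / 8-region / 6× mini
cohort run twice for bit-level determinism. These sizes were chosen so
the full suite completes on one CPU in well under half an hour while
keeping every check statistically decisive.

## Known limitations

- The random forest partially absorbs genuine dip signal where bias
  factors correlate with distance to the region center (here, the GC
  bump): recovered AOC scales linearly with tumor fraction but
  underestimates the injected depletion in absolute terms. Detection and
  correlation are unaffected; absolute dip calibration would need
  bias-factor-matched control regions.
- With few regions and shallow depth the widest Gaussian is nearly
  collinear with the intercept over the ±20 kb domain, inflating AOC
  variance; cohort σ-refitting damps but does not remove this.
- LOWESS GC correction assumes a smooth, monotone-ish trend; it will not
  fix bias that interacts with copy state.
- The S/L minimum-count floor (500) and the 5 Mb tile dropping rule
  (< 50 % non-gap coverage) are pragmatic guards, not tuned constants.
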