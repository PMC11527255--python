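# Methods

This note documents the models implemented in `rarecell`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Slide simulation and segmentation

Cells are rendered as hard disks — a cytoplasm disk with a concentric
interior nucleus disk — on a constant background with additive Gaussian
noise, one 2-D plane per channel (DAPI on the nucleus; EPI, CD45 and VAR on
the cytoplasm). Hard edges keep the area→equivalent-diameter relation
exact, which is what makes the generator usable as ground truth for
morphometry; an optional Gaussian edge blur (`edge_blur_sigma_px`) is
available to emulate optics, at the cost of a systematic diameter
inflation of roughly `2σ` per side under near-background thresholds.
Placement is rejection-sampled so cytoplasm disks never overlap (≤ 10,000
attempts per cell, then an explicit error), because the feature extractor
deliberately has no declumping stage.

Defaults describe a typical 10× slide scanner and the cell classes of a
bone-marrow liquid biopsy: 0.65 µm/px; nuclear diameter means 9 µm (WBC),
12 µm (CTC) and 32 µm (CTC-IGC); 50 WBC, 20 CTC and 2 CTC-IGC per field.
Giants are kept rare relative to typical CTCs and strongly separated in
size: if giants were a large fraction of the CTC population, they would
inflate the reference average of the 2× size rule to the point where no
cell could ever satisfy it, which contradicts the phenomenon the rule is
meant to capture. Background level 200, noise sd 20 and 16-bit output are
assumptions (scanner statistics are instrument-specific) and are all
configurable.

Segmentation is adaptive thresholding per channel — foreground iff
intensity exceeds the local arithmetic mean over a `block_size_px = 51`
window by more than `offset` (default 40 = 2× the default noise sd) —
followed by union across channels and 8-connected labeling. Objects under
`min_object_area_px = 20` are removed as debris. Intensity statistics are
computed on raw, unthresholded intensities; a per-channel background
(median, sd) over non-cell pixels is recorded for gating. FISH puncta are
counted as local maxima above background median + 5 sd inside each
nucleus, with a 3 px minimum separation.

## Phenotype gating and the CTC-IGC rule

Channel positivity is `mean > background + k·sd` with `k = 3` by default
(no numeric gates exist to inherit, so a conventional 3-sigma rule is
used); absolute cutoffs can be supplied per channel. CD45 positivity takes
precedence: any CD45+ cell is a WBC regardless of EPI. DAPI is gated on
the nucleus mean, membrane markers on the cell mean. EPI−/marker+ cells
are reported as their own category and never merged into the CTC count.

The IGC rule flags a CTC whose nuclear equivalent diameter is at least
`igc_ratio = 2` times the reference average of the typical-CTC population.
The reference is computed with a leave-one-out, iterated scheme: each cell
is compared against the mean of the *other, unflagged* cells, and flags
are recomputed until the flagged set (which can only grow) stabilizes.
This choice resolves an ambiguity in the verbal rule — "double the average
of the CTC population" is ill-defined when giants inflate the average they
are judged by — in the direction that giants cannot mask themselves: a
single 24 µm cell among ten 12 µm cells is flagged (24 ≥ 2 × 12), which a
plain all-inclusive mean would miss (threshold 26.2). A `single_pass`
config retains the one-shot all-inclusive mean, and mean/median are both
available for the reference statistic. The rule compares ratios only and
is therefore scale invariant.

A sample is IGC-positive iff at least one CTC-IGC is detected; cohort
positivity is reported as a percentage at one decimal place.

## Copy-number ratio profiles

Bin counts are modeled as negative binomial with variance `µ + αµ²` and
mean proportional to `copy_number × wgd_multiplier × gc_bias(gc)`, with a
quadratic GC bias normalized to mean 1. Defaults — 500 reads/bin over
2,000 bins (≈ 1 M reads per cell, typical for single-cell low-pass WGS)
and `α = 0.005` (about 2× Poisson variance at that depth) — are the
package's standard depth for ratio analysis. Simulated clones are heavily
aneuploid (integer copy numbers drawn per chromosome arm from {1..4} by
`random_clone_cn`): arm-level gains and losses are what make a ratio
profile identifiable, and near-diploid profiles with a single focal gain
carry too little between-bin variance for bin-level correlation to be a
meaningful clone fingerprint at low-pass depth.

GC correction fits a quadratic least-squares trend of log counts on GC
fraction per cell and rescales by `median/trend(gc)`; a constant GC vector
degrades to the identity with a warning. Ratios are `c_i / mean(c)`, so
the genome mean is exactly 1 and the transform is exactly invariant to
global scaling — the formal statement of WGD blindness. Segmentation is
per-chromosome recursive binary splitting on `log2(max(ratio, 1e-3))`,
accepting the boundary with the largest pooled two-sample t statistic when
it exceeds `penalty = 5` with `min_bins = 10` per side — conservative
choices for low-pass noise. Segment means are means of member-bin ratios,
reported untransformed. Profile similarity is the Pearson correlation of
bin ratios; clustering is average linkage on `1 − r`.

## Differential expression and the survivor set

The count model is a per-gene negative-binomial log-linear GLM with the
condition indicator, the centered per-cell detection rate (fraction of
genes with count > 0) and sequencing-batch dummies, with log effective
library size as offset; the condition term is tested by likelihood ratio
against chi-square(1) and p-values are BH-adjusted. Dispersions are
moment estimates computed within groups, shrunk on the log scale (weight
0.6) toward a quadratic mean-dispersion trend, and held fixed during
fitting. Aliased design columns are pruned; a batch fully confounded with
the contrast is an error naming the aliasing.

Effective library sizes are TMM-style trimmed means of log ratios against
a pseudo-reference (30% trim on M, 5% on abundance). Because a large,
one-sided DE fraction still leaves a residual composition bias after
symmetric trimming, the model is fit in two passes: genes found DE in the
first pass (FDR < 0.05, |LFC| > 0.5) are excluded from the size-factor
pool and the model refit. In simulations with ~15% of genes shifted
upward this removes an LFC attenuation of about 0.25 log2 units.

The survivor set is the intersection of `lfc > 1.5 and fdr < 0.01`
selections across all contrasts (both cell lines × both treatments). The
1.5 cutoff is interpreted on the log2 scale (> 2.8-fold); the base is a
documented interpretation, not an inherited constant. Intersection is
order-invariant, and within-line intermediates can be formed by
intersecting any subset of results — set intersection is associative, so
two-stage and four-way readings agree on the final set.

LFC concordance between lines is the Pearson correlation of estimated
LFCs over a gene set. Note that concordance is only informative when true
effect sizes *vary* across genes: if every shared gene had the same true
LFC, between-gene variance would be pure estimation noise and the
correlation would hover near zero even under perfect sharing. Simulation
checks therefore plant per-gene variable effects.

## Per-cell enrichment and ORA

The JASMINE-style score combines, per cell, (i) the mean rank of expressed
signature genes among all expressed genes divided by the number of
expressed genes — invariant under any monotone transform of expression —
and (ii) the odds ratio of signature vs non-signature detection, with
empty contingency margins floored at 1. Each component is min–max scaled
across cells; a degenerate all-equal component maps to 0.5; the score is
the mean of the two components. "Expressed" means count > 0; rank ties
get average ranks; a cell expressing no signature gene has rank component
0 (before scaling). Over-representation uses the hypergeometric upper
tail on overlap counts against a user-supplied GMT collection, BH-adjusted
across collections; collections disjoint from the universe are skipped
with a warning.

## Survival

Kaplan–Meier is the product-limit estimator with Greenwood variance; with
no censoring it equals the empirical survival function exactly. Ties
between events and censorings at the same time are resolved events-first
(the standard convention). The median is the first time with S(t) ≤ 0.5,
missing if never reached. The log-rank test is the two-group
observed-minus-expected statistic with hypergeometric variance at each
distinct event time, referred to chi-square(1). Expression dichotomization
defaults to a median split with ties going low (the external cut-point
conventions of public survival portals are not knowable, so median is the
neutral default, configurable).

Synthetic cohorts use exponential event times with a group hazard ratio
and independent exponential censoring calibrated so that roughly the
requested fraction of baseline-group subjects is censored.

## Expression simulation: what it does and does not emulate

Per-gene baseline means are log-normal (meanlog 3.0, sdlog 1.2 at the
2,000-gene scale), emulating deep full-length (Smart-seq2-like) libraries
in which detected genes carry tens to hundreds of counts. Counts are NB
(dispersion 0.3) around means modulated by: a per-cell technical size
factor (log-normal, sdlog 0.3) — without technical depth variation the
detection rate becomes almost collinear with the condition and the
detection-rate covariate needlessly inflates LFC variance, which real
data does not exhibit; a per-batch log2-normal gene effect (sd 0.2); the
planted survivor signature in every treated condition of both lines; and
optional line-specific signatures. Detection dropout is logistic in log
mean (slope 1.5), applied after sampling.

Not emulated: gene–gene correlation, cell-cycle or pseudotime structure,
ambient contamination, doublets, isoform-level effects, and the real
lines' distinct baseline transcriptomes (both simulated lines share one
baseline). Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful count model, not robustness to
every artifact of real single-cell data.

## Problem sizes

Standard analysis sizes used throughout the tests and the acceptance
script, chosen as the package's reference conditions: slides of
1200 × 1200 px with 72 cells; 2,000 genomic bins over 10 chromosomes;
2,000 genes × 60 cells per arm for DE (null calibration and planted-
signature recovery); 1,000 genes for concordance checks; 20 replicates
for enrichment win rates; 2,000 simulated cohorts of 60 subjects for
log-rank calibration.

## Known limitations

- The DE implementation is the described model *class* (NB GLM +
  detection rate + batch, LRT); it is validated by calibration and power
  properties, not bit-agreement with any external pipeline.
- Segmentation assumes separated cells (no watershed declumping) and flat
  illumination; the generator guarantees both.
- Binary segmentation recovers step-like (arm-scale) events; focal events
  below `min_bins` are invisible by construction.
- Absolute ploidy is out of scope: ratio profiles cannot distinguish a
  diploid from its doubled counterpart — that is the point — so ploidy
  claims require an orthogonal measurement (FISH spot counts).
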