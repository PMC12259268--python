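# Methods

This note documents the models and procedures implemented in graftquant,
the parameter choices that matter, what the synthetic generators do and
do not emulate, and the numerical conventions used throughout.

## In silico model of T cell–compartment contact dynamics

**Model.** N circular cells move on a continuous 2-D canvas with
reflective boundaries. Each moving cell advances by its speed along its
heading once per tick; headings are uniform on [0, 2π) and speeds uniform
on a configured range, both redrawn at every release. Two axis-aligned
rectangular compartments ("red", "blue") of predefined areas are placed
at seeded random non-overlapping positions (aspect ratio drawn from
[0.5, 2]). A moving cell whose center enters a compartment freezes for
that compartment's contact duration (in ticks); when the clock reaches
zero it is released one cell radius beyond the nearest compartment edge —
so it cannot refreeze on the same step — with a fresh random heading and
speed. A compartment with contact duration 0 never holds a cell.
Snapshots count frozen ("immobilized") cells only; a moving cell that
happens to lie inside a compartment is not counted.

**Physical scale.** One simulated cell diameter (2 units by default)
corresponds to 8 μm, the average CD8⁺ T cell diameter. Densities are
reported in cells/mm² using physical compartment areas under that scale;
the default 400×400-unit canvas is therefore a 1.6×1.6 mm field, and the
8000-unit² compartments are 0.128 mm² each — biopsy-like magnitudes.

**Speed regime.** The reference speed range is 60–140 units/tick, of the
order of the compartment spacing. This makes compartment encounters
area-proportional: each tick a moving cell effectively resamples its
neighborhood, so the probability of landing in a compartment scales with
its area. In the opposite (crawling) regime, encounters scale with
compartment *perimeter*, and the area-normalized density acquires a
systematic 1/√area dependence that confounds the question the model is
built to answer. Under area-proportional encounters, expected density is
n·c·d (cell number × encounter constant × duration) for *both*
compartments regardless of their areas — which is exactly why only
contact-duration asymmetry can shift the normalized difference. Speeds
remain configurable for users who want the crawling regime.

**Statistics.** Conditions are compared by one-way ANOVA on the
(red − blue) density difference, with each (seed, snapshot) pair as a
replicate, pooling snapshots so the conclusion does not hinge on the
time point chosen. An all-identical comparison is flagged degenerate
rather than assigned a p-value. The reference experiment varies one
factor at a time across three conditions (duration 1:1/2:1/4:1 at equal
areas; 400/800/1600 cells; areas 1:1/2:1/4:1 at constant total), each in
triplicate seeds with snapshots at ticks 250–400. At these settings the
duration factor is significant in essentially all replications while the
cell-number and area factors stay at the ≈5% false-positive floor; the
published experiment's exact p-value is not reproducible because the
original canvas, speed, and snapshot settings are unknown, so
significance is treated as a qualitative property.

**Density as an intensive quantity.** Scaling the whole system
geometrically (canvas and compartment areas by k, speeds by √k, cell
count by k) leaves expected physical density unchanged; this is the
meaningful normalization invariance and is what the suite tests. Scaling
compartment areas and cell count while holding the canvas fixed changes
per-cell encounter rates and is not density-preserving under any
encounter physics.

## IHC color deconvolution and CD8 density

Optical density is computed per RGB band as OD = −log₁₀((I+1)/I₀) with
I₀ = 255, then projected onto the inverse of a stain matrix whose rows
are unit optical-density vectors for hematoxylin, eosin, and DAB (the
standard published basis as shipped by scikit-image; configurable).
Negative concentrations are clipped to zero. Because the synthetic
forward model composes images as I = I₀·10^(−c·V) − 1, float renders
invert exactly (round-trip < 10⁻⁶ OD); 8-bit quantization adds ≈2×10⁻³
OD of rounding error, and concentrations whose combined OD exceeds
log₁₀(255) in any band saturate at black and cannot be recovered.

ROI segmentation applies Otsu's threshold (plus a configurable offset)
to one deconvolved channel, followed by an ordered erosion/dilation
sequence. The default is a symmetric opening (erosion then dilation,
disk radius 2 px): it removes speckle without net growth, since any net
dilation inflates the ROI area by roughly perimeter × radius and biases
density low (≈4% on tile-scale ROIs). The channel used for ROIs is
configurable — the compartment-stain (eosin-like) channel by default,
the hematoxylin channel as an alternative — because published
descriptions of such pipelines differ on this point. Manual corrections
(e.g. excluding glomeruli that stain like tubular basement membrane) are
set unions/differences on the mask.

Cells are detected on the DAB channel by scale-normalized
Laplacian-of-Gaussian blob detection with overlap suppression. The σ
range brackets the 8 μm cell diameter: σ = r/√2 in pixels ± 50%, with a
default response threshold of 0.05. A blob whose rounded center lands on
a mask pixel (boundary included) counts as inside; density is
inside-count / mask area in mm². Blob counts are non-increasing in the
threshold, and density is invariant to joint rotation of image and mask.

## Whole-slide CXCL12 gradient

Slides are covered by non-overlapping tiles (2048 px default); edge
tiles are padded with background white and padding counts as empty. An
"empty" pixel has min(R,G,B) > 220. Tiles whose empty fraction strictly
exceeds 50% are dropped. Tissue is segmented on the hematoxylin OD by a
local-mean threshold (255-px blocks, offset −0.02 OD) plus an absolute
floor of 0.05 OD that keeps uniformly pale background out. CXCL12⁺
pixels are tissue pixels with DAB OD strictly > 0.035. Slide metrics are
pixel sums over retained tiles — positive fraction = Σpositive/Σtissue,
normalized intensity = Σ(positive OD)/Σtissue — so they equal the
unsliced-image metrics when nothing is filtered and are invariant to the
tile size. Positive-region centroids are emitted as descriptive spatial
output only; no comparison is built on them because there is no
standard operational definition of a "gradient distribution" metric.
Group comparisons use the exact two-sided Mann–Whitney U distribution,
appropriate for the small biopsy groups this assay produces.

## Track kinetics

Detections are linked frame-to-frame by accepting candidate pairs within
the displacement gate in ascending distance order (ties broken by
detection index), a deterministic minimal-cost mutual-nearest-neighbor
rule; unmatched detections start new tracks and no gaps are closed.
Per-track metrics use 3-D step lengths and true timestamps: step speed =
step length / step duration (μm/min); mean velocity = total path length
/ total elapsed time (the time-weighted mean of step speeds is also
emitted); traveled distance = total path length (which bounds the
straight-line displacement from below and is exactly additive under
track splitting); arrest coefficient = time-weighted fraction of the
track below 2 μm/min. Time-weighting makes irregular sampling unbiased.
A track is labeled by its compartment and split where the label
switches. Groups are compared metric-wise by Welch's two-sided t-test
with means ± SEM.

The published in vivo values (velocities 2.8 vs 1.6 μm/min, distances
16.0 vs 8.1 μm, arrest coefficients 0.43 vs 0.65 for intravascular vs
extravascular cells) derive from movies that are not publicly
deposited; they are therefore used only as an ordering constraint —
synthetic fast/low-arrest vs slow/high-arrest regimes must reproduce the
direction (intravascular faster, less arrested) with p < 0.001 — never
as numerical targets.

## Single-cell QC and DELG partitioning

QC applies the gene filter first (keep genes expressed, count > 0, in
strictly more than 10 cells), then the cell filters on the reduced
matrix: mitochondrial UMI fraction ≤ 0.3% (strictly greater removes) and
detected genes within [300, 4000] inclusive. The 0.3% threshold is
implemented exactly as published even though it is unusually stringent
for kidney tissue; both the threshold and the mito gene set ("MT-"
prefix) are overridable. Normalization is ln(1 + count/total·10⁴).
DELGs are lineage genes with |logFC| > 0.2 and adjusted P < 10⁻⁸, both
strict; endothelial/epithelial percentages are over the DELG count (and
always sum to 100 because the lineage lists are disjoint), and two
contrasts are compared by χ² on the 2×2 lineage × contrast table without
continuity correction. Clustering, annotation, DE fitting, and GSEA are
consumed from established implementations as inputs; this module is
deliberately rules-and-bookkeeping.

## Synthetic generators: what they emulate, and what they don't

All generators are pure functions of (spec, seed).

- **IHC tiles** (512², 0.5 μm/px): one rounded rectangular compartment
  (~45% of the tile) carrying the eosin-like compartment stain over a
  hematoxylin background, with n DAB Gaussian spots (8 μm diameter,
  σ = r/√2) placed by dart-throwing at ≥16 μm separation, plus 5 decoy
  cells outside the ROI; additive Gaussian OD noise (0.02 default);
  composed by the forward Beer–Lambert model and quantized to 8 bits.
  Real tiles differ in ways the generator does not model: irregular ROI
  shapes, touching cells, stain variation between labs, and chromatic
  aberration — so recovery numbers bound performance on clean,
  well-separated stains, not on hard clinical material.
- **Gradient slides**: a hematoxylin-uniform tissue area with a linear
  DAB ramp (0→0.2 OD default), a patch-shuffled "disrupted" variant that
  preserves the OD histogram (hence fraction and intensity) while
  destroying the spatial gradient, and a uniform variant; the truth
  fraction is computed analytically on the OD field at the 0.035
  threshold. No scanner noise or stain variation is modeled.
- **Tracks**: persistent random walks (heading persistence 0.7, chosen
  to resemble meandering in vivo paths) with Markov stop-and-go
  switching: a moving cell stops with probability stop_prob per frame
  for a fixed stop duration, during which it only jitters (0.02 μm/frame,
  far below the 2 μm/min threshold at the 30 s default frame interval).
  The fast regime (8 ± 2 μm/min, stop_prob 0.10, 5-frame stops) stands
  for intravascular motility; the slow regime (4 ± 1.5 μm/min, 0.25,
  8 frames) for extravascular. The realized stop fraction per track is
  the recovery target for the arrest coefficient. Localization error
  and track fragmentation are not modeled.
- **Count matrices** (5000 genes × 300 cells default): gamma-Poisson
  (negative binomial, dispersion 1) counts with gene means uniform on
  [0.1, 2], 13 near-silent mitochondrial genes, and planted violations —
  low-gene cells (100 expressed genes), high-gene cells (>4000),
  high-mito cells (mito spike), rare genes (5 cells). Margins are wide
  enough that ordinary cells and genes pass QC with overwhelming
  probability, so planted labels serve as exact truth. Doublets,
  ambient RNA, and batch effects are not modeled.

## Problem sizes and tolerances

The test suite and the acceptance script use: 10⁴ pixels for the
deconvolution round-trip (< 10⁻⁶ OD); 100 IHC tiles × 30 cells
(recovery ≥ 95%, density error ≤ 10%); one 2048² gradient slide
(fraction within 2% of truth, 512-vs-2048 tiling within 1%); 50
replications of each three-condition simulator experiment (duration
significant in ≥ 90%, the others below) plus a triplicate symmetric run
(density ratio within 1 ± 0.1); 100 + 100 synthetic tracks (stop-fraction
recovery within 0.05, regime separation p < 10⁻³); and one 5000 × 300
count matrix with 12 planted cell violations and 10 rare genes (exact
agreement). These sizes keep the full run to a few minutes on one CPU
while leaving comfortable statistical margins at each stated tolerance.

## Known limitations

- The simulator's conclusions depend on the encounter regime (see
  above); the crawling regime is supported but has different area
  scaling.
- Deconvolution assumes the stain basis is known; stain-vector
  estimation from images is out of scope.
- The tracker has no gap closing; fragmented detections yield split
  tracks rather than interpolated ones.
- Published headline numbers that depend on undeposited movies and
  slides are treated as qualitative ordering constraints only.
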