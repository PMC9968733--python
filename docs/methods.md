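# Methods

This note documents the models, defaults and design choices behind
`chondroprint`, in the order the pipeline runs.

## Synthetic cell populations

Each cell is modelled as an ellipse with optional cytoplasmic processes and
a circular nucleus.

* **Major axis** *L* ~ lognormal with mean `mean_length` and CV 0.25.
* **Aspect ratio** AR = 1 + X with X ~ lognormal (mean `mean_ar_excess`,
  CV 0.35). The shifted-lognormal form keeps AR ≥ 1 by construction, which
  an independent lognormal minor axis could not guarantee; the minor axis is
  W = L/AR.
* **Processes**: count ~ Poisson (mean 2.0 per cell for controls); each
  process is a capsule anchored on the ellipse boundary with length
  ~ U(1.5, 4.5) µm (processes are short, ≤ 5 µm) and width ~ U(1.2, 1.8) µm.
* **Nucleus**: diameter ~ N(10, 1) µm, clipped to at most 0.75·W so it
  always fits inside the cell.

Control parameters: bovine healthy cells use mean length 35 µm and mean AR
1.7; human osteoarthritic cells use mean length 40 µm and mean AR 2.0 (the
two cell sources differ in every descriptor; only the bovine control length
is pinned by a published value, the human values are a stated modelling
choice). Within-population CVs are not published — 0.25 (morphology) and
0.30 (expression) are explicit, overridable defaults.

### Treatment effects

A preset stores the published per-descriptor multiplicative effects on
population means. The generator has two independently controllable
morphological degrees of freedom — mean area and mean aspect ratio — plus
the process rate. Effects are realized as:

* AR: X is scaled by m_g = (r·(1+g) − 1)/g so that E[AR] changes by exactly
  the aspect-ratio effect r (g = control mean of X).
* L: scaled by sqrt(a·κ), where a is the area effect and
  κ = E[1/AR_ctrl]/E[1/AR_treated] (computed by Gauss–Hermite quadrature),
  so that E[area] = E[π/4·L²/AR] changes by exactly a. This is the
  "symmetric axis split": area and aspect-ratio effects are controlled
  independently.
* Process rate: multiplied by the preset's protrusion-rate effect (0.7 for
  the human preset, 0.5 for the bovine 10 ng/ml preset), standing in for
  the published circularity increases (fewer/smaller processes).

The remaining descriptor entries (width, length, circularity, roundness,
solidity multipliers) are descriptive consequences of these three dials,
not separately enforced: for ellipses roundness = 1/AR and width = L/AR
follow automatically, and the realized changes agree with the published
values to within one or two percentage points.

## ddPCR expression tables

Per-sample concentrations (copies/µL) are lognormal around
`control_mean × donor_effect × fold^condition`. Samples are paired by donor
— each donor contributes one control and one treated sample, as in the
underlying experimental design — and the noise is split into a donor-shared
lognormal effect (CV 0.25) and an independent residual (CV ≈ 0.16), chosen
so the total within-group CV is 0.30. The split matters: the donor effect
cancels in the paired ratio treated/control, leaving only the residual's
Jensen bias E[T/C] = fold·exp(σ_residual²) ≈ 1.026·fold, so mean paired
fold changes recover the preset values closely. Fully independent noise at
CV 0.3 would bias the mean ratio upward by ~9%.

Genes whose controls are essentially unexpressed (median control below
0.5 copies/µL) are reported in raw copies/µL instead of as ratios — the
bovine IL-8 preset (control mean 0.3 copies/µL) exercises this path.

## Rendering and noise

Tiles are rasterized at 1.5 µm/px by default (a 10× objective with ~3×
downsampled sensor gives a comparable scale). Ground truth is the binary
pixel-center rasterization; cells are composited in order, later cells
occluding earlier ones, and per-pixel ownership plus each visible cell's
true descriptor panel (measured from the raster by the morphometry module
itself) are recorded. Cell centers keep a 25 µm minimum spacing: adherent
cells in a subconfluent monolayer spread side by side, so bodies may touch
but nuclei do not stack.

Intensity: stain density ramps from ~25% at the membrane to 100% over
2.5 µm into the cell (smooth falloff), with per-cell brightness jitter
U(0.9, 1.1), Gaussian PSF blur σ = 0.5 px (≈ 0.75 µm, consistent with a
10×/0.45 NA objective), Poisson photon noise (scale 200), Gaussian read
noise (SD 0.01) and constant background 0.08. These defaults were chosen so
that the default classifier reaches ≥ 95% pixel accuracy (tested) and
boundary placement is accurate enough for effect-size recovery; the flat
alternative (constant intensity to the cell edge) systematically dilated
thin structures after blurring.

What the generator does **not** emulate: optical PSF physics beyond a
Gaussian, ddPCR droplet Poisson statistics, cell migration or time
dynamics, uneven illumination, and within-cell texture. Passing tests
therefore demonstrate correctness of the *analysis* under a controlled
image model, not robustness to every real-microscopy artifact.

## Segmentation

Features per channel: raw intensity plus Gaussian-smoothed intensity,
gradient magnitude and Laplacian at σ ∈ {1, 2, 4} px (configurable) —
20 features for two channels. The classifier is an ensemble of 40
extremely-randomized trees (seeded, single-threaded); the pipeline contract
is only "probabilistic 3-class pixel classifier", so alternatives plug in.
Scribbles for synthetic scenes are sampled from the interior (1 px erosion)
of each ground-truth class, as a user annotates away from ambiguous
boundaries. Ties in the posterior argmax resolve toward background (class
order background < cytosol < nucleus).

Instances: markers are 4-connected nucleus components of ≥ 9 px; watershed
floods the inverted cytosol posterior (or an inverted distance transform if
no posterior is available), constrained to predicted foreground.
Foreground blobs with no marker are kept as single instances and logged.
Instances below 50 µm² are treated as debris and removed; instances
touching the tile border are removed by default because their descriptors
are truncated. Label ids are consecutive, scan-ordered, and the whole stage
is deterministic.

All tiles of an experiment are processed with one classifier trained on a
single control tile — the analysis processes every tile rather than a
manually chosen subset of "representative" images, a deliberate departure
from interactive practice.

## Morphometry

* Axes come from the ellipse with the region's second central moments
  (with the 1/12 per-pixel variance correction), so "length" and "width"
  are the moment-ellipse major/minor axes. Aspect ratio (elongation) is
  L/W and is distinct from length itself.
* Perimeter uses a chain-code step estimator (orthogonal steps weighted
  0.948, diagonal 1.340), unbiased for digitized discs; raw crack-boundary
  counting would deflate circularity by ~10% for round cells.
* The convex hull is taken over pixel corners, not centers, so convex
  rasterized shapes (e.g. filled rectangles) have solidity exactly 1.
* Circularity and roundness are clamped at 1 (discretization can
  marginally exceed it).
* Degenerate inputs: empty or multi-component masks are errors; label-map
  instances that arrive split (possible after occlusion in ground-truth
  rasters) are measured on their largest 4-connected fragment.

## Statistics

* Normality gate: Lilliefors-corrected Kolmogorov–Smirnov (the plain KS
  test with estimated mean/SD is anti-conservative). Groups with n < 4 or
  zero variance are routed to the rank test.
* Two groups: pooled-variance Student's t when both groups pass the gate at
  α, else Mann–Whitney with tie-corrected normal approximation and
  continuity correction; all-tied inputs return p = 1.
* More groups: Kruskal–Wallis (tie-corrected) with Dunn's mean-rank z
  statistics for all pairs; pairwise significance is gated on the omnibus.
* No multiple-testing correction by default (single-comparison α = 0.05
  convention); Holm adjustment is available for correlograms.
* Correlograms: Spearman whenever either variable is categorical/ordinal
  (condition 0/1, donor, grade), Pearson otherwise; constant variables
  yield missing entries. For single-cell correlograms the sample's
  treatment class is broadcast to its cells (the data carry no per-cell
  treatment reading — a stated convention).
* Fold changes are reported as mean ± SEM of per-donor ratios.

## Fingerprinting

Features are column z-scored (the heatmap color key is in SD units).
The CIM clusters rows and columns by complete-linkage hierarchical
clustering on Euclidean distances (average and Ward available); a
2-cluster row cut is cross-tabulated against the condition classes.

PLS-DA is a from-scratch NIPALS fit against the centered 0/1 class column;
X is centered as well. For a univariate response each component's weight
has the closed form w ∝ Xᵀ(y − ȳ) on the deflated data; the iterative loop
(tolerance 1e-10, ≤ 500 iterations, deterministic initialization from the
class column) is kept for the general multi-response case. Score signs are
normalized so every component's score correlates positively with the class;
a positive component-1 loading therefore marks the treated class, a
negative one the control class, and |loading| ranks importance — the
tabular analog of loading-bar plots. Default depth is 2 components
(visualization convention); importance is read from component 1 only.
Scores are pairwise orthogonal (checked to 1e-8) and with
ncomp = min(n−1, p) the centered X is reconstructed to 1e-6.

One caveat on rankings: after z-scoring, every feature with a near-perfect
class separation (IL-6 at 82×, IL-8 at 147×, COL2A1 at 0.1×, …) carries an
almost identical |loading|, so the order *among* those saturated features —
and among near-null features — fluctuates between replicates. Class
assignments and the identity of the top features per class are stable
across seeds (tested over 10 replicates); an exact total order of all 13
features is not a meaningful invariant under these conditions.

## Problem sizes and determinism

The acceptance script uses 200 replicate ddPCR experiments for fold-change
recovery and ≥ 1500 interior cells per condition for image-pipeline
recovery, rendered as 800×800 µm tiles at the preset seeding densities
(9375 cells/cm² human, 3000 cells/cm² bovine). Control and treated image
groups are *paired*: the same population seed generates both, with only the
treatment multipliers differing — mirroring the donor-matched design in
which one cell isolate is split into control and treated wells, and
cancelling population-sampling noise from the effect-size estimates. The
bovine control group doubles as the control-length estimate. Every random
draw descends from the single `--seed` through named substreams; rerunning
any stage with the same inputs is bit-reproducible.

## Known limitations

* The image model is a stylized monolayer; confluent cultures, debris,
  uneven illumination and out-of-focus light are not modelled.
* Segmentation merges occasionally survive where overlapping cells share an
  occluded nucleus; these inflate a small fraction of instance areas.
* The percent-change estimator through the full image pipeline carries a
  residual attenuation of 1–2 percentage points on elongation-sensitive
  descriptors (blur erodes the tips of elongated cells); this is within the
  stated recovery tolerances but visible in matched-pair diagnostics.
* Donor is treated as exchangeable; no mixed-effects modelling.
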