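# Methods

This note records the models the package implements, the parameter choices
that matter, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## TIL maps and their two scales

A TIL map is a 2-D grid; each cell summarises one 50×50-pixel tile of a
whole-slide image.  The binary scale stores 0/1 TIL calls; the probability
scale stores 0 for negative tiles and the classifier's confidence in
[0.5, 1] for positive ones.  A valid probability map thresholded at 0.5
reproduces the binary map, and the package treats the two as views of the
same slide: point/graph statistics use the TIL membership (identical across
scales), while Moran's I, the GLCM sums and spatial chaos use the stored
values and therefore respond to the scale.

## Preprocessing

**Size filter.** Maps with fewer than 10,000 patches are dropped before
anything else (a 100×100 map is kept: the filter is `< 10,000`).  Real
whole-slide images are far larger; tiny files are crops or failures.

**Line artifacts.** Scanner lines appear as a full row or column of
TIL-positive patches.  The per-line TIL counts are compared by a discrete
second difference: line *i* is flagged when its count exceeds the mean of
its two neighbours' counts by more than 20% of the line length (border lines
compare to their single neighbour).  Flagged lines are *deleted* — the grid
shrinks — rather than zero-filled, so a fake line can never leave a void
that splits one tissue region into two ROIs.

The 20% rule is *relative to the image size*, with a consequence worth
stating: it is idempotent at the scale it was applied at (a cleaned full map
contains no further detections) but must not be re-applied to the tightly
cropped ROIs it produces.  A dense crop has line lengths of roughly twice
the fragment radius, and at that scale ordinary binomial density
fluctuations exceed the threshold in about half of simulated maps.
Detection therefore runs once, on the full map, before cropping; the test
suite pins both the map-level idempotence and the exactness of repeated
segmentation/cropping.

**ROI segmentation.** The TIL-positive mask is closed with a 3×3 structuring
element (so stippled tissue coheres while fragments separated by more than
~3 patches stay apart), labelled with 8-connectivity, and each component's
*original* TIL patches (not the closed ones) define its area and bounding
box.  Components below 10% of the slide's total TIL-positive area are
treated as background speckle and dropped; survivors are cropped tight and
masked to their own component so overlapping bounding boxes cannot leak
patches between ROIs.  This conserves total TIL area up to the dropped
specks exactly.

## The measures

All measures operate on a cropped ROI.  Every patch becomes a point at its
grid coordinate (unit spacing); TIL membership is `value > 0` (binary) or
`value ≥ 0.5` (probability).

**Ripley F, G, L (r = 50).**  G is the fraction of TIL points whose nearest
TIL neighbour is within r; F is the empty-space function evaluated on the
full unit grid; K is the unscaled pair count normalised by window area and
n(n−1), reported as L = √(K/π).  No edge correction is applied — the single
fixed radius is used comparatively across ROIs, not as an absolute estimate.
The uncorrected estimator is biased low when r is comparable to the window
(at r = 50 on a 300×300 CSR window, mean L ≈ 46.6 instead of 50), so the
implementation also offers toroidal (periodic) distances; with them the CSR
expectation L(r) = r is met to Monte-Carlo precision (measured 49.98 ± 0.27
over 50 replicates), which is how the estimator is validated.  Production
default remains non-periodic.  On desk-scale ROIs (≲100 patches across)
F(50) and G(50) saturate at 1 for any non-trivial pattern; they are computed
faithfully and then removed by the variability screen, which is the expected
behaviour, not a defect.

**Moran's I.**  I = (n/S₀)·Σ wᵢⱼ zᵢzⱼ / Σ zᵢ² with binary, row-unstandardised
weights from a symmetrised k-NN graph (k = 6, a common default for lattice-like
spatial data; configurable).  A constant field returns NA rather than 0 —
zero variance means the statistic is undefined.  A 0/1 checkerboard under
rook weights gives exactly −1 regardless of standardisation, which the tests
exploit as a closed-form anchor.

**Group centralities.**  Everett–Borgatti group definitions for the TIL node
set: degree = fraction of non-TIL nodes adjacent to ≥1 TIL node; closeness =
(number of reachable non-TIL nodes) / (sum of their BFS distances to the TIL
set), with unreachable nodes excluded and the count adjusted; average
clustering = mean local clustering coefficient over TIL nodes.

**Affinity propagation + validity indices.**  AP on TIL coordinates with
similarity = −squared Euclidean distance, preference = median similarity,
damping 0.9, ≤500 iterations (scikit-learn).  AP is O(n²) per iteration, so
patterns above `max_points` (default 5,000) are clustered on a seeded
uniform subsample and the rest assigned to the nearest exemplar; the demo
pipeline uses a lower cap (1,000) to keep its runtime in seconds — the cap
trades exemplar granularity for time and is always logged.  Non-convergence
falls back to one cluster per connected component of the k-NN graph, logged.
The four indices are authored here: Ball–Hall (mean over clusters of mean
squared distance to centroid), Banfeld–Raftery (Σ nₖ log(tr(Wₖ)/nₖ); a
zero-scatter cluster contributes −∞, preserved), C-index ((S_W −
S_min)/(S_max − S_min) over the N_W within-cluster pairs; NA on a degenerate
denominator) and determinant ratio (det T / det W_G; +∞ when W_G is
singular, e.g. collinear points).  NA/∞ propagation is deliberate: these
states carry information (degenerate clusterings) and downstream stages
drop them explicitly.

**GLCM M1/M2.**  Values are quantised to 8 equal-width levels over the ROI's
[min, max]; a symmetric co-occurrence matrix is accumulated at distance 1 in
four directions (0°, 45°, 90°, 135°) and normalised.  M1 weights the
low-intensity quarter with w\_{ij} = (9−i)(9−j) and M2 the high quarter with
w\_{ij} = i·j — low co-occurring pairs and high co-occurring pairs each
scored with emphasis on the extremes.  The weight matrices are injectable,
since texture-score weightings are a tuning surface by nature.  Constant
ROIs quantise degenerately and return NA.  A two-level checkerboard is the
instructive hand case: horizontal/vertical neighbours always mix levels
(mass at (1,8)) while diagonal neighbours always repeat them, so M1 = 64·p₁₁
and M2 = 64·p₈₈ are small but strictly positive.

**Spatial chaos.**  Two-step edge detection (smoothing prefilter → Sobel
magnitude → Otsu threshold), then the mean nearest-neighbour distance among
edge pixels.  Coherent structures produce contiguous edge bands and scores
near 1; scattered intensities produce sparser, partly isolated edge pixels
and higher scores.  The prefilter defaults to a Gaussian (σ = 1 patch)
rather than a 3×3 median: on coarse binary patch grids the median filter
either erases sparse patterns outright or leaves plateaus whose Sobel edges
are unbroken bands, collapsing the score to exactly 1 for structured and
chaotic patterns alike; Gaussian smoothing keeps the gradient field
continuous so Otsu isolates only the strongest edges.  Median and
no-prefilter variants remain available.  Two honest caveats.  First, on a
pixel lattice *any* contour-based edge set is mostly 8-connected, so the
score lives in a narrow band (≈1.00–1.4) — "high chaos" means 1.05, not 10.
Second, the clustered-below-random ordering is real but the weakest of the
directional properties: at matched density it holds in roughly 65–75% of
paired draws (sign-test significant over 20 pairs, but close to the
boundary), whereas the Ripley-L and Moran orderings hold essentially always.

**%TIL.**  Fraction of TIL-positive patches of the ROI grid.

## Patient aggregation and screens

ROI values are averaged per patient *unweighted* — a size-independent
measure should agree across fragments of the same tissue, so weighting by
ROI area would only dilute disagreement that the reproducibility screen is
supposed to see.  NA/∞ values are excluded from the mean rather than
poisoning it; an all-NA patient stays NA.

The robust CV is |MAD/median| with the unscaled MAD; a zero median makes it
undefined (NA).  The screen excludes a measure when its median across-patient
CV falls below 10⁻⁶ (no signal to model) or its median across-ROI CV exceeds
2 (ROIs of one patient disagree by more than twice the typical value).  Both
thresholds are configuration, since the underlying judgment is qualitative;
on CV tables with the structure reported for real pan-cancer TIL cohorts the
defaults exclude exactly Ripley F, Ripley G, average clustering and the
determinant ratio, leaving 10 measures, with Banfeld–Raftery additionally
restricted to probability-scale maps in the survival defaults.

## Survival evaluation

Measures are min-max scaled to [0, 1] after dropping NA/∞.  The discretized
scenarios choose a cutpoint by the minimum-p-value method: 30 equally spaced
*quantile levels* between 0.10 and 0.90 (equally spaced raw values are the
config alternative), binarise at each (≥ t → 1), fit a ridge-penalized Cox
model with age, record the Wald p of the binary coefficient, and keep the
argmin (ties to the smaller threshold; thresholds leaving a group with no
events are skipped).  The selected p is the minimum of ~30 dependent tests
and is anti-conservative by construction; the full p-curve is returned so a
multiplicity correction can be applied by the caller — the pipeline itself
deliberately reports the uncorrected value, as the method is defined.

All Cox fits use lifelines' `CoxPHFitter` with an L2 penalty of 0.1 — one
fixed value across all scenarios rather than per-case tuning, accepting a
known shrinkage (a true log-hazard of 0.7 on a [0,1] covariate at n = 500 is
recovered at ≈0.60 ± 0.04; unpenalized, ≈0.66).  Harrell's C is taken from
the fitted model's risk score with ties counted 0.5.  Fits with fewer than
10 usable patients, no events, a constant measure or a convergence failure
produce an NA row with a reason, never an exception.  Ranking is by
descending C within each (cancer, endpoint, model, measure scale, map scale)
block, average rank on ties, then averaged across blocks.

## The synthetic generator

What it emulates: multiple disjoint tissue fragments per slide (discs),
full-row/column line artifacts, small background speckle below the 10% area
rule, CSR versus Matérn-style clustered TIL placement (parents Poisson,
offspring uniform in a disc), both map scales with slide-level variation in
classifier confidence (TIL probabilities 0.5 + 0.5·Beta(a, b) with (a, b)
drawn per slide — without this, probability values are exchangeable across
slides and cross-scale rank correlations are trivially 1), and survival
cohorts with Weibull baseline (shape 1.2, scale 1500 days), a linear or
step effect of a chosen driver measure, an age effect (0.02/year, centred),
and independent censoring.

Default map conditions: 160×160 patches, two radius-24 fragments, within-
fragment TIL density 0.55 (TIL-dense tissue, above the site-percolation
threshold so fragments segment as single components), one artifact line,
three specks of ≤4 patches.  The clustered fill draws offspring in rounds
until the realised cell count matches density × fragment area, because
offspring collapsing onto shared grid cells would otherwise leave clustered
maps several-fold sparser than their CSR partners; when the parent discs
cannot hold the target the fill saturates into dense aggregates, so nominal
density is an upper target under extreme parameters.  Matched-density
ordering experiments use density 0.08 with 12 parents of radius 6 inside a
radius-35 fragment, where capacity comfortably exceeds target.

What it does not emulate: nucleus-level morphology, staining variation,
spatially correlated classifier errors, adjacent serial sections of the same
fragment (ROI pairs are independent fragments), or cancer-type-specific TIL
biology.  Passing tests therefore demonstrate that the *machinery* is
correct and recovers planted structure and effect sizes — not that any
particular measure is prognostic in real tissue.

## Numerical and API decisions

- NA is `numpy.nan`, infinity `numpy.inf`; TSV round-trips spell them `NA`
  and `Inf`/`-Inf`.
- Coordinates are 0-based (row, col), rows increasing downward.
- One global pipeline seed fans out to per-stage seeds by fixed offsets; AP
  is the only stochastic measure stage.  Same seed ⇒ bit-identical maps,
  cohorts and result tables (the manifest stores SHA-1 hashes to prove it).
- Binarisation boundary is `value ≥ threshold → 1` everywhere.
- `det(W_G)` below 10⁻¹² in absolute value counts as singular (→ ∞).
- The k-NN graph symmetrises the directed k-NN relation (union), weights 1,
  no self-loops; ties at equal distance resolve by scikit-learn's stable
  neighbour ordering, so results are reproducible across runs on the same
  platform.

## Problem sizes

Tests and the reproduction script run on deliberately small instances — maps
of 80–200 patches a side, cohorts of 200–500 patients, 10–50 replicates per
property — chosen so the whole suite exercises every stage, including the
quadratic brute-force oracles, in a few minutes on a single core while still
giving the statistical checks (sign tests, recovery rates, Monte-Carlo
bands) enough power to fail loudly when the implementation is wrong.

## Known limitations

- The uncorrected Ripley estimator is comparative, not absolute, at radii
  near the window size; use the periodic option for absolute calibration.
- Spatial chaos has limited dynamic range on coarse binary lattices (see
  above); it is most informative on probability-scale maps.
- The minimum-p selection p-values are anti-conservative and are reported
  as such; the exported p-curve is the hook for correction.
- Affinity propagation above the subsample cap clusters a subsample; exemplar
  sets (and hence the validity indices) depend mildly on the cap and seed.
- The screening thresholds encode a qualitative judgment; different cohorts
  may need different floors/ceilings, which is why they are configuration.
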