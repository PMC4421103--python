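# Methods

## Scope and model

The package classifies five tissue types on single 2D grayscale brain
slices: WM, GM, CSF (healthy) and tumor, edema (pathological).  The
underlying model is intensity-based: each tissue is assumed to occupy a
quasi-homogeneous intensity range, with interfaces detectable as
gradient ridges, the tumor core as the brightest compact blob, and
edema as a band of intermediate intensity around it.  No atlas, no
multi-contrast information and no 3D context are used; these are
explicit non-goals.

## Synthetic phantom

Clinical scans for this recipe are not publicly deposited, so the
package ships a phantom generator that emulates the geometry the
pipeline assumes: concentric discs — background (0), a thin dark
skull/scalp ring, a CSF rim, a GM annulus, a WM core — plus an optional
tumor disc with an edema annulus inside the WM core.  Default mean
intensities (8-bit scale) are background 0, skull 25, CSF 50, GM 110,
edema 150, WM 200, tumor 245; i.i.d. Gaussian noise (default sd 4) is
added and clipped to [0, 255].  The generator validates that all means
are pairwise ≥ 3·sd apart and that the lesion fits inside the WM core,
and is a pure function of its spec (same seed ⇒ bit-identical output).

What the phantom does *not* emulate: bias fields, partial-volume
averaging at interfaces, anatomical shape variability, multi-focal or
infiltrating lesions, and Rician (rather than Gaussian) MR noise.
Passing the synthetic suite therefore demonstrates correctness of the
operators under the stated intensity model, not clinical performance.

The end-to-end experiment uses 30 slices (20 train / 10 test) at noise
sd 4 with lesion center, radius (10–14 px) and halo width (5–7 px)
varied per slice from the run seed; slices are 192×192 px.  These sizes
keep the full experiment comfortably light while leaving every tissue
with dozens of feature blocks.

## Preprocessing

*Skull stripping.*  The dark ring sits between the air background and
the darkest brain tissue in intensity and is attached to the brain, so
no single global threshold separates it.  The recipe works outward-in:
a triangle threshold (robust when a zero background dominates the
histogram) delimits the head; closing, largest connected component and
hole filling consolidate it; the ring intensity is then estimated from
the head's outermost 1-px layer and the brain's dark end from a
6-px-eroded core (10th percentile), and when they differ by more than
`ring_gap` (default 10 gray levels) the mask is re-cut at their
midpoint.  Interior pixels that fall below the cut return via hole
filling, so brain retention is ~100%.  When no dark ring is detected
(the two estimates agree), the head mask is used unchanged — a
ring-free image passes through identically.  A final erosion is
available (`erode_px`, default 0) for real data with fuzzy boundaries.

*Histogram equalization* maps intensities through the exact empirical
CDF of the nonzero pixels onto [0, 255].  The exact CDF (rather than a
binned approximation) keeps the mapping strictly monotone and
idempotent, properties the downstream thresholds rely on; zeros
(stripped background) are excluded so they cannot compress the brain's
dynamic range.

## Segmentation operators

*Gradient / edge map.*  Gaussian smoothing (default sigma 0.5 px)
followed by central differences.  The small default sigma keeps the
edge-exclusion band around tissue interfaces ~1 px wide; at the
intensity separations the model assumes (gaps ≥ 10 noise sd) a wider
kernel buys no additional robustness while costing boundary pixels in
every mask.  The edge threshold defaults to Otsu on the within-brain
gradient magnitudes.

*WM/GM dichotomy.*  Non-edge brain pixels at or above an intensity cut
are WM, below it GM.  The automatic cut is an exact between-class
-variance (Otsu) scan over the distinct intensity values, returning the
midpoint of the optimal gap.  The exactness matters: binned Otsu
implementations return a bin center that can land a fraction of a gray
level below an intensity mode on noise-free images, silently flipping
that whole tissue across the cut.  Note the raw dichotomy lumps CSF
(dark) into GM; the orchestrator subtracts the CSF/tumor/edema masks
afterwards.

*CSF.*  The sine transform `sin(3u/100)² + 0.05·rand(i)` (u = intensity
rescaled to [0, 100], rand uniform per pixel, seeded) responds low for
dark CSF; the mask is the brain pixels at or below
`csf_threshold · max(I_cf)` (default fraction 0.45).  A light Gaussian
pre-smoothing (`csf_smooth_sigma`, default 1 px) suppresses
pixel-level noise before the transform; the random term is kept as
specified.

*Tumor.*  Region growing from an automatic seed (centroid of the
brightest blob — top percentile after equalization), 4-connected,
admitting a neighbor when its intensity is within `rg_tolerance`
(default 25 gray levels) of the running region mean.  The running mean
(rather than the seed value) is the standard noise-robust variant.  If
the grown region exceeds `max_tumor_fraction` (default 0.25) of the
brain, the "tumor" is just bright normal tissue and the image is
reported as lesion-free rather than an error.

*Edema.*  Equalize, keep the intensity band `t₄ ≤ p ≤ t₃` (capped by
the tumor-core floor `t₅`), keep only pixels at distance ≥ `t₆` from
the tumor centroid, then dilate and close (radius 1).  Automatic
thresholds: `t₆` is the tumor equivalent radius `sqrt(area/π)`; `t₄`
and `t₃` are the 2nd/98th percentiles of the equalized intensities in a
3-px ring just outside the tumor core — the region the distance logic
itself designates as peritumoral.  (A plain multilevel Otsu was
rejected: rank-based equalization maps a small edema class nearly onto
the much larger GM class, and variance-based splitting merges them.)
Finally, pixels whose raw intensity deviates from the mask median by
more than `trim_mad` (default 4) median-absolute-deviations are
dropped: the dilation sweeps a 1-px ring of neighboring tissue into the
mask, which would otherwise contaminate the region's variance feature
with mixture spread that training on expert masks never exhibits.

*Orchestration.*  Tumor first (its centroid and area parameterize
edema), then edema, CSF, WM/GM; pathological and CSF masks are
subtracted from the healthy ones so each pixel belongs to at most one
tissue.

## Features

Blocks are 8×8 (even, so the level-1 wavelet halves cleanly) and
qualify at ≥ 50% nonzero pixels; partial edge blocks are dropped.  Per
block: M and E are the mean and population variance of the nonzero
pixels; I is the modal-bin fraction and S the least-squares slope of
the occupied bins of a 32-bin histogram over [0, 255]; H, V, D are the
mean absolute Haar level-1 detail coefficients of the full block
(zeros included — spatial layout matters for the wavelet).  "Histogram
intensity" and "histogram slope" have no canonical definition in this
recipe's literature; the modal-fraction/envelope-slope reading is the
package's documented choice.  Haar is the wavelet default because its
two-tap filters make the toy oracles exact.  The tissue vector is the
unweighted mean over qualifying blocks; a tissue with no qualifying
block is reported absent rather than failing the image.

## Swarm feature selection

Particles are continuous gating vectors in [0,1]⁷ (thresholded at 0.5
for subset extraction); velocities are clamped to ±`v_max`.  Besides
the textbook personal-best and global-best attractions, the velocity
update carries a personal-worst repulsion `C₁ᵥᵥ·r₂·(S − Pworst)∘Pworst`;
the trailing elementwise `∘Pbest` / `∘Pworst` factors are applied as
specified, with `classic_terms=true` dropping them to recover the
textbook update (used by the reduction-equivalence test).  Iteration 1
evaluates the initial swarm, so `max_iter=1` returns the best initial
particle; global-best ties break to the lowest particle index.

The fitness of two feature vectors groups (I, S, M) as squared
differences normalized by `n_f − 1` and (E, H, V, D) as absolute
differences weighted by `√(n_f − 1)`, under one square root.  Any
admissible grouping must be symmetric, nonnegative and zero at
identical vectors; this particular one is pinned and tested.  As a
selection objective the distance is evaluated between the gated target
-class mean and the gated mean of the remaining classes (features are
z-scored first), so maximizing it maximizes class separation.  A
wrapper objective (leave-one-out nearest-centroid accuracy on the gated
features) and arbitrary callables are also accepted.

Defaults: 20 particles, 100 iterations, inertia 0.72, C₁ᵦ = C₂ = 1.49,
C₁ᵥᵥ = 0.5, v_max = 0.5 — standard constricted-PSO territory with a
half-weight worst term; none of these is prescribed by the recipe
itself.

One property of the grouped distance deserves note: every term is
nondecreasing in every gating weight, so the objective's true optimum
is all-ones, and a feature is dropped only when its weight drifts below
0.5 stochastically.  Because the squared group (I, S, M) is divided by
`n_f − 1` while the absolute band (E, H, V, D) is multiplied by
`√(n_f − 1)`, the objective constrains the band features far more
strongly; I, S and M can therefore drop out of a subset even when
individually discriminative.  The classifier tolerates this on the
phantom experiment, but runs where parsimony or stability of the
subset matters should prefer the wrapper objective.

## Per-class networks

One 1-hidden-layer sigmoid network per tissue (default 10 hidden
units), trained one-vs-rest on the z-scored selected features by
seeded per-sample gradient descent (learning rate 0.1, ≤ 2000 epochs).
The optimization target and stopping rule use the mean squared error
(tolerance 1e-3); the signed mean residual `L = (1/H_d)·Σ(D − Z)` is
logged per epoch as specified but is not the descent objective, since
opposite-signed residuals cancel (L = 0 with MSE = 1 is possible).
Initialization is Xavier-style and seeded; training is bit-reproducible
given seed, data and config.  Classification takes the argmax of the
five activations with ties resolved by the fixed order WM, GM, CSF,
tumor, edema.

## Evaluation

The evaluation unit is one segmented tissue sample of one image: each
test slice contributes up to five feature vectors, so one-vs-rest
confusion panels per tissue have TP+FP+TN+FN = 5 per slice.  Derived
statistics (percent scale): sensitivity TP/(TP+FN), FPR FP/(FP+TN),
accuracy (TP+TN)/total, specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN), FDR FP/(FP+TP) and the standard Matthews correlation
coefficient.  A 0/0 rate is reported as 0 and flagged degenerate.
Display rounding is half-up to integers except FPR and MCC at one
decimal; full precision is kept internally.  Aggregates are arithmetic
means rounded half-up to integer percent.  Mask quality is summarized
by the Dice coefficient 2|A∩B|/(|A|+|B|).

## Reproducibility and numerical choices

A single top-level seed derives all module seeds through
`numpy.random.SeedSequence` (children reduced below 2³¹); phantom
generation, the CSF random term, swarm initialization and updates, and
network initialization/shuffling all descend from it.  Degenerate
inputs are handled explicitly: all-zero images, empty brain supports,
single-class training targets and absent tissues raise or are reported
absent as documented.  Gradient correctness of the backpropagation is
held to 1e-6 against central finite differences.

## Known limitations

Intensity overlap between tissues (strong bias fields, low SNR) breaks
the threshold operators before it breaks the classifier; the CSF
transform assumes 8-bit-range inputs; region growing assumes a single
compact bright lesion; the training/testing asymmetry (expert masks vs
algorithmic masks) transfers only because the segmentation is accurate
on the intensity model — on real data the two feature distributions can
drift apart, and the MAD trim on the edema mask is the only guard
against that drift built into the pipeline.
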