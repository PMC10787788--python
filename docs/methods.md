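# Methods

## Data model

The pipeline consumes three inputs: a detected-transcript table (continuous
`x, y` in pixel units, a gene identifier, and an optional phred-scaled
quality `qv`), a nuclei instance-label mask (integers on an H×W grid, 0 =
background; upstream nuclei segmentation is taken as given), and a reference
cell-type × gene mean-expression matrix with a per-type "elongated" flag.
Transcripts with `qv < 20` are removed (records with no `qv` are kept — the
threshold is strict, so `qv = 20` passes), as are records whose gene name
contains a control-probe substring (`NegPrb`, `Blank-` by default). The
survivors are rasterised into an H×W×n_genes count tensor by flooring the
continuous coordinates onto half-open pixel intervals; pixel (i, j) is
(row, col) = (y, x), 0-based. Rasterisation conserves counts; out-of-bounds
and off-panel records are dropped and counted. The default scale is 1 µm per
pixel and is configurable; nothing downstream depends on the physical scale.

## Nucleus typing and expansion masks

Each nucleus's expression vector is the column sum of the map over its
pixels. Typing is the argmax over reference types of the Spearman rank
correlation between that vector and each reference row (average ranks at
ties; argmax ties broken by type-name order; zero-variance vectors fall back
to an `unknown_round` type treated as non-elongated). An ellipse is fitted
to every nucleus by the second-order central moments of its pixel
coordinates (plus 1/12 per axis for the within-pixel variance); axes are 4·√λ
of the covariance eigenvalues, the eccentricity is √(1 − b²/a²), and the
orientation is the major-axis angle reported modulo π.

The cell-calling target for a round-type cell is one binary dilation of its
nucleus with a disc inscribed in a 20×20 window. For an elongated-type cell
the kernel is an ellipse with full axis lengths l_h = α·ecc·l_t and
l_v = l_t − l_h when that exceeds l_vm, else l_vm (α = 0.9, l_t = 60 px,
l_vm = 3 px; both floored at 1 px), rasterised as the pixels inside the
rotated ellipse and rotated to the nucleus orientation. Expansion masks are
computed once on the full image and cropped per patch, so a cell crossing a
patch border keeps its full geometry.

## Markers

Positive and negative markers per type are the top and bottom
⌈percentile·n_genes⌉ genes (default percentile 0.10) of a differential
score: mean log1p expression of the type minus the mean over the other
types. Ties at the boundary break lexicographically; a boundary gene claimed
by the positive set is skipped by the negative set so the two are disjoint.
Positive markers shared across types are removed: for training markers when
present in at least one third of types (inclusive), for evaluation markers
when present in strictly more than 25%. In both cases a gene must appear in
at least two types' sets before it can count as "common" — with very few
types the literal fraction would otherwise remove every marker, including
type-unique ones. Per cell and patch, marker maps are binary indicators of
any marker transcript at a pixel, masked by the cell's expansion mask, then
dilated with a 3×3 structuring element.

## Backbone and prediction

The reference backbone is a three-level encoder–decoder in NumPy: 3×3
convolutions (He-normal init) with leaky ReLU (slope 0.1), two 2× average
poolings, nearest-neighbour upsampling, skip connections at both resolutions,
and a 1×1 convolution to two logit channels. Width (16 by default) and depth
are configuration, not contract: any registered backbone that maps
(n_cells, n_genes + 1, h, w) to (n_cells, 2, h, w) can be used. Each batch
element is the shared raw-count expression patch (no normalisation)
concatenated with that cell's binary nucleus mask — the nucleus channel is
what lets the network distinguish cells sharing a patch. Softmax over the
two channels yields per-cell foreground/background probabilities.

For a patch's segmentation, background probabilities are averaged across
cells and a pixel-wise argmax is taken over {mean background, each cell's
foreground}; ties favour background, then the lowest cell id. For n_cells = 1
this reduces to thresholding foreground against background at 0.5.

## Losses

All six losses act on the per-cell soft foreground probabilities q̂ (clipped
to [1e−7, 1−1e−7] before logarithms) and return analytic gradients; the
finite-difference checks in the test suite exercise the same code path as
training.

- `L_ne`: one binary cross-entropy between the patch's union nucleus mask
  and the aggregated prediction (per-pixel mean of the per-cell
  foregrounds). Aggregating matters: it dilutes the off-nucleus penalty on
  any single cell by 1/M, which is what permits cells to grow cytoplasm
  beyond their nuclei while still being anchored to them.
- `L_cc`, `L_pos`: per-cell BCE against the expansion mask and the dilated
  positive-marker map, averaged over the M cells of the patch.
- `L_os`: p_nuc,c = Σ_ij σ(q̂·x_nuc − 0.5), p_cyto,c = Σ_ij σ(q̂·(1−x_nuc) − 0.5);
  the loss is (1/M)Σ_c(p_cyto − p_nuc) if that sum is positive, else 0.
- `L_ov`: s_ij = −(1−x_ij) + Σ_c σ(q̂_ijc(1−x_ij) − 0.5) with x the union of
  nuclei; the loss is Σ_ij s_ij/(M·h·w) if the total is positive, else 0.
  The positivity condition is applied to the total, not per pixel.
- `L_neg`: (1/M)Σ_c Σ_ij σ(q̂·m_neg − 0.5). Non-marker pixels contribute a
  constant σ(−0.5) floor with zero gradient; the same gradient-free offset
  appears in `L_ov` on nucleus pixels. Both are implemented verbatim.

Reduction scale. The cross-entropy losses are **pixel sums** (with the 1/M
cell average where the formulas carry it), the same per-pixel scale as the
sigmoid-sum losses. This is deliberate and load-bearing: with pixel-*mean*
cross-entropies the growth signals (cell calling, positive markers) are
h·w-fold weaker than the shrinkage signals (over-segmentation, overlap,
negative markers), and at equilibrium the cytoplasm foreground provably
cannot exceed the argmax threshold M/(M+1) — training then converges to
nuclei-only segmentations. We verified this failure mode empirically before
fixing the scale. A `reduction="mean"` option exposes the per-pixel average
(ln 2 at a uniform 0.5 prediction) for the closed-form identities.

The total is the λ-weighted sum with every λ = 1. Any non-finite component
aborts training, naming the component and step.

## Training

Only primary-grid patches containing at least one nucleus are used. Each
step draws one patch (shuffled per epoch, cycling when iterations exceed the
number of patches — small images are revisited, unlike full-scale images
where every training patch is distinct) and applies one of the eight
dihedral transforms (optional horizontal flip × rotation by 0/90/180/270°),
uniformly at random, consistently to the expression patch, nucleus masks,
expansion masks, and marker maps. Expansion and marker maps are precomputed
once per patch since they do not depend on model state.

Optimisation is Adam at a fixed learning rate with β = (0.9, 0.999) and
classic L2 weight decay 1e−4 added to the gradient. Gradients are clipped to
global norm 1.0: at initialisation the softmax predicts 0.5 everywhere, the
hinge losses are active at full pixel-sum scale, and without clipping (and
without the leaky slope) the first steps collapse the small network to a
saturated all-background state it cannot leave. Full-scale defaults are 4000
iterations at learning rate 1e−5; the scaled-down configuration used in the
end-to-end test and the README example is 300 iterations at 1e−3, chosen to
keep the product of rate and steps comparable on a single-CPU budget. One
global seed drives weight initialisation, shuffling, and augmentation; runs
are bit-reproducible.

## Inference, refinement, transcript assignment

Both patch grids are predicted (patches with no nuclei yield no cells).
Per pixel, the merged label comes from the patch whose centre is nearest;
iteration order (primary grid first, then ascending origin) with a strict
improvement rule makes the tie-break deterministic. Each cell is then
refined: two dilations followed by two erosions with a disc inscribed in a
5×5 window (pixels lost only to image-border erosion are restored — closing
is extensive on the infinite plane); among 4-connected components the one
with the largest nucleus overlap is kept (ties: larger component, then scan
order); its holes are filled; the nucleus is unioned back in. Every final
cell is one 4-connected component containing its nucleus; a cell whose raw
prediction is empty or disjoint from its nucleus falls back to the nucleus
alone. Refined cells are pasted into one label image in ascending-label
order, first claim wins on contested pixels, and nucleus pixels are forced
to their own label; overlapping refined neighbours are rare at the simulated
densities but would be resolved by that ordering.

Transcripts are assigned to the cell whose mask contains their pixel,
producing the n_cells × n_genes matrix (CSV or MatrixMarket with index
sidecars) and the fraction of transcripts assigned. Assigned plus background
always equals the total.

## Evaluation framework

Per-cell baselines: transcript and gene counts, area (px²), density = Σnᵢ/A.
Shape metrics are computed on a polygon traced from the mask boundary
(marching squares, then a 5-point circular moving average to remove the
half-pixel staircase so rasterised discs converge to the analytic
identities): elongation = W_bb/H_bb of the oriented minimum-area bounding
box (axis-aligned optional); circularity = 4πA/P²_convex;
sphericity = R_I/R_C (maximum inscribed over minimum enclosing circle
radius); compactness = 4πA/P²_cell; convexity = P_convex/P_cell;
eccentricity = L_minor/L_major from the exact polygon second moments
(Green's theorem); solidity = A/A_convex. The eccentricity follows the
formula (1 for a circle, smaller for flatter cells) rather than the
inverted prose ratio. Degenerate shapes report missing values.

Expression purity: each cell's top/bottom expression deciles (ties by gene
order; zero-count genes eligible for the bottom decile) are scored against
its type's evaluation markers (precision/recall/F1); per-type average F1
scores combine into purity F1 = 2·(1−F1_neg)·F1_pos/(1−F1_neg+F1_pos),
defined as 0 when the denominator vanishes. The averages are already in
[0, 1], so the "scaling" before the combination is the identity; an optional
across-method min–max is exposed. Concordance with the reference uses
Pearson correlation of mean log-normalised expression (library-size scaled
to 10⁴, then log1p) per type, plus the correlation of type-proportion
vectors; types with fewer than two cells report missing.

Spatial diversity grids the image into 10×10 regions (configurable), assigns
cells by centroid, computes the Shannon entropy (natural log) of each
region's type composition and the coefficient of variation of each cell
characteristic (regions with fewer than three cells excluded), and reports
the entropy-vs-CV Pearson correlation across regions. Neighbour
contamination bins type-A cells by Euclidean centroid distance to the
nearest type-B cell and reports the fraction expressing a chosen type-B
marker per bin. Replicability correlates per-type means of each baseline
characteristic, and type proportions, between two replicates.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, so that
training, inference, and evaluation run without any external download. Cells
are non-overlapping ellipses (rotation uniform, rejection-sampled placement
with a bounded attempt budget that fails with an explicit density message);
eccentricities are drawn from a high range (0.85–0.97) for elongated types
and a low range (0–0.6) for round types, mirroring the observation that
elongated cell types have more eccentric nuclei. Nuclei are concentric
ellipses scaled to 30% of the cell area. Per-cell transcript counts are
Poisson; gene identities follow the type's profile; positions are uniform
within the cell mask; background noise is uniform in space and gene
(0.001 per px² by default). All randomness flows from one seed and outputs
are bit-identical across runs.

Reference profiles use a block-marker design: genes are partitioned into
⌈n_genes/n_types⌉-sized blocks; a type's own block is enriched 20-fold and
the other types' blocks are depleted 20-fold relative to a uniform(0.5, 1.5)
baseline. The depletion is essential, not cosmetic: the negative-marker loss
assumes a type's negative markers are genuinely rare in its cells (true of
curated SST gene panels); with a flat baseline those genes appear at normal
rates and the loss suppresses foreground inside the cells it should grow.
Types additionally differ 1.5-fold per step in total RNA content, so
per-type baseline characteristics are distinguishable — without this the
replicability correlations would be correlations of pure noise.

What the generator does not emulate: optical point-spread functions,
z-stacks, platform-specific misassignment or crosstalk, irregular
(non-elliptical) cell shapes, spatial niche structure, and cell-type
dependent density gradients. Passing tests therefore demonstrate that the
implementation is faithful and that the method recovers cells when its
assumptions hold; they do not certify performance on any real platform's
data.

## Numerical choices and limitations

Probability clipping 1e−7 before logarithms; σ is the logistic function.
The nucleus-channel conditioning, the nearest-centre patch merging, the
floor binning of sub-pixel coordinates, and the disc-inscribed reading of
"20×20 circular kernel" are this package's resolutions of points the method
description leaves open; each is deterministic and documented where
implemented. Elongated types are declared in configuration per tissue — no
attempt is made to auto-detect them. Typing happens once, before training;
there is no iterative re-typing after segmentation. The morphological
refinement guarantees nucleus capture even where the model under-covers a
nucleus, which means the number of output cells always equals the number of
nuclei — split or merged nuclei in the input propagate to the output.
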