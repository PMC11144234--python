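# Methods

`postfire` assesses the effect of a wildfire on vegetation from
vegetation-index rasters in four stages: bi-temporal change detection,
multi-year trend analysis, soil-based regrowth prediction, and generative
recovery mapping.  All four are validated against synthetic scenes with
known ground truth; this note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish.

## Raster model and vegetation classes

Rasters are aligned 2-D grids (row 0 at top) of index values with an
explicit boolean nodata mask; georeferencing is carried as opaque metadata
and never used for computation — reprojection, atmospheric correction and
cloud masking are assumed done upstream.  NDVI = (NIR−Red)/(NIR+Red);
EVI = G(NIR−Red)/(NIR + C1·Red − C2·Blue + L) with the usual MODIS
coefficients (G=2.5, C1=6, C2=7.5, L=1), exposed as arguments.

NDVI is thresholded into five vegetation classes.  Published range tables
for this scheme overlap at the low/moderate boundary (0.24 vs 0.25); we
resolve the scheme as half-open intervals

| class | interval |
|---|---|
| no vegetation | [−1, 0) |
| bare | [0, 0.1) |
| low | [0.1, 0.25) |
| moderate | [0.25, 0.4) |
| high | [0.4, 1] |

which covers [−1, 1] totally and deterministically: every unmasked pixel
gets exactly one class.

## Change detection: sparse autoencoder + deep embedded clustering

Both epochs are classified into the five classes; each unmasked pixel
becomes a patch feature (default 3×3, reflect-padded, class codes scaled
to [0,1]) over its class map.  Features of *both* epochs are pooled and
clustered by one shared Deep Embedded Clustering model with k = 5 (one
cluster per vegetation class); a pixel is *changed* when its two epochs
receive different cluster labels.  Pooled training rows are sorted
lexicographically before subsampling, so the fitted model — and therefore
the binary map — is invariant to swapping the epochs.

The feature encoder is a sigmoid dense autoencoder (default widths
9→16→4) trained with mean-squared reconstruction error plus a sparsity
penalty on the bottleneck: either L1 (λ·Σ|a|, per-sample batch average) or
the Bernoulli KL between a target rate ρ and each unit's batch-mean
activation ρ̂_j,

KL(ρ‖ρ̂_j) = ρ ln(ρ/ρ̂_j) + (1−ρ) ln((1−ρ)/(1−ρ̂_j)),

clamped to ρ̂_j ∈ [1e−7, 1−1e−7].  Defaults: KL mode, ρ = 0.1, weight
0.05, 150 epochs of Adam at 1e−2, batch 256.  Setting the weights to 0
recovers a plain autoencoder exactly.

DEC then uses the Student-t kernel soft assignment
q_ij ∝ (1+‖z_i−μ_j‖²/α)^−(α+1)/2 (α = 1) and the sharpened target
p_ij ∝ q_ij²/f_j with cluster frequencies f_j = Σ_i q_ij, alternating
target updates (every 30 epochs) with full-batch Adam steps on KL(P‖Q)
over both encoder weights and centroids (closed-form gradients, verified
by finite differences in the tests).  Training stops when under 0.1% of
points change hard assignment between target updates.

Numerical choices worth knowing:

* **Embedding standardization.**  Bottleneck codes are column-centered and
  divided by their global standard deviation, frozen at initialization.
  The sparsity penalty can compress codes into a small corner of [0,1]^d
  where pairwise distances are ≪ 1; there the unit-bandwidth t-kernel is
  nearly flat and the KL refinement can merge real clusters.
  Standardization keeps distances O(1) at any sparsity level.
* **Degenerate inputs.**  With ≤ k distinct embedding points (e.g. both
  epochs identical), each distinct point becomes its own centroid and
  refinement is skipped — identical inputs always produce an empty change
  map.  Otherwise centroids come from seeded k-means (10 restarts),
  re-seeded up to 5 times if a cluster comes up empty.
* The within-interval KL objective is monitored; it jumps upward at each
  target update (P is re-sharpened), which is expected, and decreases
  within each interval.

## Trend analysis: Sen's slope

Per-date rasters are composited to annual maxima (nodata-aware; an
optional month filter restricts the season).  Per pixel, the trend is
Sen's slope — the median of all pairwise slopes (x_j−x_i)/(t_j−t_i),
i < j, with years as the abscissa, so irregular gaps are handled by the
formula; an even pair count yields the mean of the two central slopes.
Pixels with fewer than two valid years are nodata.

A pixel is *greening* when slope > `zero_band` and *browning* when
slope < −`zero_band` (default 0; published fraction pairs that do not sum
to 1 imply an implicit neutral band, which this parameter makes explicit).
Areas are counts × (pixel_size_m/1000)² km².  No Mann–Kendall significance
test is applied — classification is by magnitude only, matching the
method's definition; a significance filter would be a straightforward
extension.

## Regrowth prediction: stacking ensemble

Five base learners — logistic regression, SVC (RBF, calibrated
probabilities), decision tree, random forest (200 trees), Gaussian naive
Bayes — are cross-fit with stratified 5-fold CV and a logistic-regression
generalizer is trained on their out-of-fold class probabilities only
(scikit-learn `StackingClassifier`), so meta-features never contain
in-fold predictions; shuffling the labels collapses held-out accuracy to
the majority rate, which the tests check.  Numeric soil attributes (pH,
nitrogen, organic carbon, bulk density) are standardized; the soil group
is one-hot encoded, with unknown groups at prediction time mapped to the
all-zero encoding and flagged.  Latitude/longitude are excluded by default
(they index location, not soil quality) behind an `include_coordinates`
flag.  `fit_stack` reports held-out metrics on a stratified 25% split.

## Recovery mapping: conditional adversarial network

The recovery mapper is a conditional GAN on temporal pairs: input = a
post-fire composite at time t, target = the composite at t+Δ.  A trained
generator therefore maps a single post-fire image to its predicted
recovered state.

*Generator*: `n_down` (default 3) stride-2 4×4 convolutions doubling
channels from `base_channels` (default 16); a gated-residual self-attention
block (queries/keys at C/8 channels, scalar gate initialized to 0 so the
network starts as a plain encoder-decoder — this stabilizes small-data
training) after the third downsampling stage; mirrored nearest-upsample +
3×3 conv stages with *summation* skip connections from the matching
encoder stages; dropout (0.3) in every decoder stage; tanh output, so
values live strictly in (−1, 1).

*Discriminator*: PatchGAN over the 2-channel (input, candidate) pair —
three stride-2 leaky-ReLU (slope 0.2) convolutions with batch
normalization after the first and instance normalization after the second
and third, then a stride-1 convolution to a 1-channel patch-logit grid
(8×8 for 64×64 input; no global pooling).

Training alternates one discriminator step (BCE on real/fake pairs) and
one generator step (non-saturating adversarial loss + `rec_weight`·L1 to
the target, default 50) per batch, Adam (β₁ = 0.5, lr 2e−4), with
L2 weight regularization (1e−5) on all convolution kernels of both
networks included in both losses.  Inference disables dropout and is
deterministic; rasters larger than the model tile are processed with
half-tile-overlap averaging.  All layers are NumPy with manual
backpropagation, so a fixed seed gives a bitwise-identical loss log on a
fixed machine.

Evaluation metrics: MAE, MSE, RMSE (=√MSE), MSLE (both grids shifted by
+1 so logarithms are defined on [−1,1] data), and the Huber loss

Huber(r; δ) = ½r² if |r| ≤ δ, else δ(|r| − ½δ),

with δ = 1 by default; the branches agree at |r| = δ (both δ²/2).  The
residual diagnostic is a Breusch–Pagan test (squared residuals regressed
on fitted values, statistic n·R², χ²₁), verdict "homoscedastic" when
p > 0.05, "degenerate" when the fitted values are constant.

## Synthetic study scenes

The generators emulate the data regimes the pipeline targets and carry
their own ground truth:

* **Burn pairs** (default 64×64 at 250 m): background = Gaussian-filtered
  white noise scaled to mean NDVI 0.65 ± 0.05 — dense pre-fire vegetation —
  plus i.i.d. sensor noise (sd 0.02); the post image depresses a random
  star-shaped polygon scar (~25% of pixels, shoelace-rescaled to the exact
  target area) by 0.5, a class-crossing burn signal.  Truth = the
  rasterized scar.
* **Trend stacks** (64×64 × 10 years): 60% of pixels get slope
  +0.01 yr⁻¹, 40% −0.01 yr⁻¹, noise sd 0.002 (slope ≫ noise); truth
  records the exact per-pixel slopes and fractions.
* **Recovery pairs** (200 × 32×32): the target relaxes the scar toward the
  background by a recovery coefficient (0.6), so at zero noise
  MAE(input, target) = coefficient × depth × scar fraction.
* **Soil tables** (n = 2000): attributes uniform over field-plausible
  ranges (pH 3–9, nitrogen 0–1, …); label = [5.5 ≤ pH ≤ 7.5 and
  nitrogen > 0.3], flipped with probability 0.05.  The analytic label
  prevalence (≈ 0.26) is checked by Monte Carlo.

What passing these tests shows: the estimators recover the quantities
they claim (slopes, fractions, scar masks, decision rules, recovery
mappings) under realistic noise at desk scale, with correct algebra and
reproducibility.  What they do not show: performance on real composites —
the scenes have no clouds, co-registration error, phenology, mixed pixels,
sensor drift or spatially correlated label noise, and the networks are
small (dense 9→16→4 encoder; 32×32 GAN tiles, three downsamplings).
Larger networks and tiles are reachable through the config objects.

## Problem sizes and reproducibility

Default sizes (64×64 scenes, 4096-row DEC training subsample, 200-pair /
30-epoch GAN runs, n = 2000 soil tables) were chosen so that the full
validation suite completes in a few minutes on one CPU core while leaving
all effects far above their noise floors.  Every stochastic component
draws from a `numpy.random.Generator` seeded from its config; scikit-learn
estimators receive the same seed; there is no hidden global state, so all
results in the test suite and the acceptance script are bitwise
reproducible on a fixed machine.
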