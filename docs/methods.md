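# Methods

## The reference-state model

The pipeline assumes a screen with two reference states — a disease-like
control (here: GFP-progerin expressing fibroblasts, non-targeting siRNA)
and a healthy-like control (GFP-progerin repressed) — and asks, for every
perturbation, what fraction of its cells looks healthy-like. Because
single-cell feature distributions of the two controls overlap strongly,
the classifier is anchored not on the full control populations but on
their *typical cells*.

**Typical cells.** Within one control population on one replicate plate,
the typical set of a channel is the core of `n_typical` (default 300)
cells with the smallest L1 (Manhattan) distance to the per-channel
population mean, computed on raw metric values. Selection precedes any
z-scoring because the z-transform itself is defined from the selected
cells. By default each metric is divided by its population SD inside the
L1 sum (`l1_prescale`) so that a single high-magnitude metric (e.g. Area
in squared pixels) cannot dominate the distance; the unweighted distance
is available by flag. Ties are broken by ascending (well, cell_id) for
determinism. Control wells are pooled per plate before selection, and the
whole procedure runs independently per replicate plate.

**Normalization.** Per metric, the mean and sample SD (ddof = 1) of the
*pooled* typical cells of both classes define a z-score transform; it is
applied both to the SVM training cells and to every cell later scored.
Pooling both classes is required so that the between-class separation
survives the rescaling.

**Boundary.** A linear soft-margin SVM (C = 1 by default; `svm_c`
configurable) is trained on the z-scored cores, labels healthy = +1.
The stored boundary has a unit normal with the SVM scale folded into the
offset, so `w·z + b` is the signed Euclidean distance in z-space; the
sign convention (healthy positive) is enforced against the healthy-core
mean. Metric importance is `|w_i| / Σ|w_j|`; channel importance sums the
shares over a channel's metrics. Importance shares of near-hard-margin
SVMs are sensitive to support-vector noise in uninformative metrics — at
the default C = 1 with ~300-cell cores, the summed share of 18
uninformative metrics can reach ~0.25. Analyses that interpret group
shares quantitatively should use a softer margin (C ≤ 0.01), which drives
the solution toward a regularized class-mean difference and suppresses
the noise shares; the importance tests do exactly that.

**Boundary stability.** Stability of the boundary *direction* is measured
by bootstrap: the angle `arccos |cosθ|` (folded to [0°, 90°] because
directions are orientation-ambiguous across trainings) between each
retrained normal and a reference normal trained once on the original,
non-resampled selection. Two selection modes are compared: `random`
draws `n_cells` per class uniformly without replacement per replicate;
`typical` resamples the full control population with replacement and
re-applies typical-cell selection, so the stability of the entire
procedure — selection plus training — is measured. By default the
selection and the SVM run within each channel's own metrics and the angle
is taken between per-channel normals (`train_scope="per_channel"`).
A full-space variant (one SVM on all metrics, angles between the
restrictions of the 21-dimensional normals to each channel's coordinates)
is available via `train_scope="full"`, but is not the default: the weight
noise of a channel's uninformative metrics inside the full-space normal
dominates its restriction and inflates every channel's angle severalfold,
masking the stability of the channel's own boundary.

**Scoring and hit calling.** A sample's score in a channel is
`100 × #(w·z + b > 0) / #cells`, computed separately per replicate plate
with that plate's boundary, then averaged unweighted over the (default 4)
replicates. Hits must pass two criteria after a cytotoxicity filter:

* threshold — replicate-mean percentage above `mean + k·SD` (k = 5) of
  the disease-control samples' replicate-mean percentages. By Chebyshev's
  inequality the probability that any null sample exceeds a 5-SD
  threshold is below 1/k² = 0.04, with no distributional assumption.
* FPR — the lower-tail probability `Φ((threshold − m)/s)`, with m, s the
  sample's replicate mean and SD, must be below 0.05. A normal tail is
  used because 4 replicates are far too few for resampling; a Student-t
  tail (df = n−1) is available by flag. At s = 0 the limit is 0 if
  m > threshold, else 1.
* cytotoxicity — a well is excluded when its replicate-averaged cell
  count falls below 50% of the healthy-control mean count (replicate-
  averaged across plates, which equals the screen-wide mean under the
  balanced design).

The healthy-control lower line (`mean − k·SD` of the repressed controls)
is reported for annotation only and plays no role in hit calling.

**Multi-channel integration.** Per-cell healthy flags in all four channels
give the "healthy in all channels" fraction (a conjunction, hence never
above any single-channel fraction) and, for each primary channel, the
fraction healthy in the other three. The combined analysis re-runs the
whole pipeline once on the concatenation of every channel's metrics,
re-selecting typical cells on the concatenated vector (reuse of
per-channel cores is available by flag).

## Synthetic data

The generator works at two levels.

*Feature level.* Cells are drawn from class-conditional Gaussians over the
21 metrics (12 shape + 3 intensity × 3 channels), on a standardized scale:
class separations are expressed directly in pooled-SD units. The default
structure gives each channel one strongly separating metric (Δ = 1.5
pooled SD; overlap coefficient 2Φ(−0.75) ≈ 0.45), one weakly separating
(Δ = 0.3), and leaves the remaining metrics uninformative and independent.
A screen is 4 replicate plates of a 384-well layout — 12 disease-control
wells (10% healthy-like cells), 12 healthy-control wells (90%), 320 siRNA
wells — with 500–2000 cells per well drawn uniformly. Each siRNA well has
a planted `rescue_fraction`, the probability that a cell is drawn from the
healthy-like class; one latent class label per cell drives all channels
(an independent-per-channel mode exists for integration tests). Unlisted
siRNA wells sit at the disease-control level.

*Image level.* Nuclei are rendered as filled ellipses with optional radial
sinusoidal lobes (amplitude as a fraction of the local radius), a
lamin-like boundary band, a uniform progerin-like interior and focal spots
for the DNA-damage-like channel, plus Poisson–Gaussian noise; masks,
contours and per-nucleus parameters are returned as ground truth. The
image path and the feature path are checked against each other: metrics
extracted from rendered shape classes separate in the metrics their specs
differ in.

What the generator does *not* model: correlations among real morphometric
metrics (real Area/Perimeter/axis lengths are strongly collinear; the
generator's uninformative metrics are independent), spatial plate effects,
illumination gradients, segmentation errors at realistic densities, and
any mechanistic link between marker intensities and shape. Passing tests
therefore demonstrate the statistical machinery under the stated feature
structure, not performance on real images.

A consequence worth stating explicitly: with only 2 informative of 12
independent DAPI metrics and 300-cell cores, the information floor for
estimating the boundary direction in the DAPI subspace is ≈ 6–8° mean
bootstrap angle — the typical-cell mode cannot reach the < 5° stability
seen on real data in that channel, precisely because real shape metrics
are collinear (low effective dimensionality) while the synthetic ones are
not. The 3-metric channels reach 2.5–4.5°, and the typical-vs-random
contrast holds in every channel.

## Morphometry definitions and numerics

* Circularity `P²/(4πA)` (circle = 1); tortuosity = boundary arc length /
  convex-hull perimeter (≥ 1, convex = 1); solidity = area / hull area.
* Eccentricity and axis lengths come from the covariance matrix of the
  polygon interior, computed in closed form by Green's theorem
  (major = 4√λ₁, matching the ellipse convention major = 2a).
* Curvature: the contour is resampled to 1-px arc-length spacing, x(t)
  and y(t) smoothed with a circular moving average (default 9 vertices),
  and κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2} evaluated with periodic central
  differences. Positive = locally convex. Smoothing biases the curvature
  of a radius-R arc by ≈ sin(w/2R)/(w/2R); at the default window this is
  < 4% for R ≥ 10 px.
* Invaginations: maximal circular runs of κ < −0.02 px⁻¹ lasting ≥ 3
  vertices. Mean Negative Curvature averages strictly negative κ only
  (0 when the contour is convex).
* Contours traced from masks (marching squares at the 0.5 level) are
  resampled and lightly smoothed (window 5) to remove the pixel staircase,
  which otherwise inflates perimeter-based metrics by ~4–5%.
* Segmentation: Gaussian blur σ = 2 px → Otsu → hole filling → watershed
  on the negated distance transform (peaks detected on a σ = 2-smoothed
  distance map to avoid plateau-induced over-splitting) → area filter
  [500, 15000] px → border-touching labels dropped. All constants are
  arguments.
* The boundary-intensity band is the set of mask pixels within 2 px
  (inward) of the mask boundary. The DAPI-derived mask is applied
  unchanged to the other channels.
* Degenerate inputs: constant images segment to zero nuclei; zero-area or
  self-intersecting contours are rejected at construction; zero-variance
  metrics abort normalization with the metric named; empty samples raise
  rather than scoring 0.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_typical` | 300 | core size per class, per channel, per plate |
| `n_bootstrap` | 200 | resamplings in the stability analysis |
| `hit_sd_multiplier` | 5 | threshold offset in disease-control SDs |
| `fpr_threshold` | 0.05 | replicate-variation false-positive cut |
| `cytotoxicity_fraction` | 0.5 | minimum cell count vs healthy controls |
| `svm_c` | 1.0 | SVM soft-margin cost |
| `l1_prescale` | on | SD-weight metrics inside the L1 selection |

## Problem sizes

The stability analyses run on 5000 cells per class with 200 bootstrap
resamplings; screen-level analyses (null calibration, planted-hit
recovery) generate full 4-plate, 344-well screens with 500–2000 cells per
well (~1.7 M cells) and are repeated over 5 seeds. These sizes were chosen
so the complete suite runs comfortably on a single CPU.

## Known limitations

* The FPR model treats 4 replicate percentages as normal; it is a rough
  estimate by construction, and the t option changes hit counts near the
  threshold.
* Typical-cell selection by L1 core assumes a unimodal "typical" state;
  multi-modal control populations would need a different core definition.
* No plate-spatial normalization (B-scores) and no multiple-testing
  correction beyond the stated criteria.
* Metric importance from `|w|` shares is margin-regularization dependent
  (see above); treat shares as qualitative at the default C.
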