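# Methods

This note records the models, the parameter choices that matter, what the
synthetic data does and does not emulate, and the numerical decisions made
where the design was open. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

The chain is resample → median filter → Otsu foreground → z-score →
rescale, applied identically before slice selection and segmentation.

- **Resampling** is trilinear to a 1 mm isotropic grid (`target_mm`
  configurable); output dimensions are `round(dim · spacing / target)`.
  Masks are resampled nearest-neighbour. `grid_mode` resampling preserves
  the physical field of view, so an affine intensity ramp is reproduced
  exactly at interior voxels.
- **Median filter** radius is 1 voxel (3³ window, nearest-border padding).
  No radius is canonical for this step; 1 voxel removes impulse noise
  without eroding a structure that is only a few voxels thick, which the
  temporalis can be.
- **Otsu threshold** is computed by an exhaustive sweep of the interior bin
  edges of a 256-bin histogram, with class statistics taken from the raw
  data (not bin centres) so that the foreground rule `v > t` is exactly
  consistent with the class split. Ties break toward the lower threshold.
- **Z-score** statistics are computed over the Otsu foreground only: with
  roughly two thirds of a head volume being air, whole-volume statistics
  would be dominated by the background spike.
- **Intensity standardization** is a robust linear rescale mapping the
  0.5th/99.5th percentiles to [0, 1] with clipping. Inside `preprocess`
  the percentile anchors are computed over the *whole volume*, not the
  foreground: the 0.5th foreground percentile is essentially the darkest
  tissue value, and anchoring it to 0 collapses the background/tissue gap.
  That makes the chain unstable under re-application (a second pass
  re-thresholds inside the head); with whole-volume anchors the chain is
  quasi-idempotent (second-pass change ≈ 0.7% RMS on the reference
  phantom, tested). The standalone `rescale_intensity` accepts an optional
  mask for the foreground-anchored variant.

## Slice selection

The measurement slice (superior orbital roof level) is found by offset
regression on maximum-intensity-projection (MIP) slabs: 5 mm thick, resized
to 256×256. A training example is a MIP centred at candidate index `i`
labelled with `offset = (target − i) · spacing_z` in mm — labels in mm keep
spacing changes transparent.

At inference the pipeline sweeps a candidate band (default: the central
third of the volume, stride 2) and converts each predicted offset into an
implied target `i + offset/spacing_z`. The final index is the rounded
median of the implied targets. Median aggregation has a 50% breakdown
point, so isolated bad predictions cannot move the slice; the robust spread
(1.4826·MAD, in mm) is reported as `dispersion_mm` and a warning is logged
above 4 mm — within that craniocaudal window the thickness measurement is
insensitive to the exact slice because the muscle is extruded nearly
vertically at that level.

The reference regressor is a single-hidden-layer MLP (64 units) on 32×32
downsampled, per-image-standardized MIPs, trained with Adam on MSE loss for
30 epochs, batch 64, learning rate 1e-3. Per-image standardization matters:
MRI intensities are arbitrary-unit, and without it the regressor keys on
absolute intensity statistics that shift with noise level and fails to
generalize across scan quality. The `SliceRegressor` contract accepts any
drop-in model with `fit`/`predict_offset`.

## Segmentation

The selected slice is upscaled to 512×512 and predicted four times through
overlapping tiles displaced diagonally by ±d (default d = 16 px, bound
d ≤ tile/8). Tile predictions are binarized at 0.5 and accumulated into a
per-pixel vote grid; a pixel is positive on a strict majority (ties
negative — conservative for thin structures). The ≥3-votes-per-ROI-pixel
property is verified by exhaustive counting at layout-construction time,
never assumed; with four diagonal placements the coverage count per pixel
is a product of per-axis window counts (1, 2 or 4), so a verified layout in
fact covers the ROI four times. Voting suppresses tile-edge artifacts: in
tests, flipping 10% of oracle probabilities per prediction still yields
Dice ≥ 0.95 after voting.

Post-processing: midline split along the left–right axis by component
centroid (components straddling the midline by more than 25% are assigned
by centroid with a warning), then the largest 8-connected component per
side. An empty side is *flagged*, not raised, so batch runs degrade
gracefully.

Training uses the focal Tversky loss with soft counts,
`TI = TP/(TP + α·FN + β·FP)`, `loss = (1 − TI)^(1/γ)`, defaults
α = 0.7, β = 0.3, γ = 4/3 (the usual recommendation: weight false
negatives harder for small structures). At α = β = 0.5, γ = 1 the loss is
algebraically `1 − soft Dice`, which the tests exploit as an oracle.

The reference segmenter is a per-pixel logistic model over a fixed filter
bank (intensity, intensity², Gaussian-smoothed intensity at σ = 2, 4, 8 px,
Sobel gradient magnitude, normalized |x|/|y| position) trained by a
hand-written Adam loop directly on the focal Tversky loss. It is
deliberately minimal — enough capacity to overfit phantom geometry
(training Dice ≥ 0.8 within 30 epochs on CPU is asserted), enough realism
to exercise every pipeline contract (probabilities, tiling, voting). It is
not a clinical segmenter and no claim about real-MRI Dice follows from it;
the `Segmenter` contract is the seam where a full encoder–decoder network
would plug in.

## Morphometry

TMT is the minimum Feret diameter: the minimum over directions of the
distance between two parallel supporting lines. The minimum width of a
convex polygon is attained flush with a hull edge, so rotating calipers
over the convex hull edges is exact. The independent test oracle sweeps
projection directions on a 0.1° grid and polishes the best cells by nested
grid refinement (the width profile has V-shaped minima where golden-section
methods stall at a √eps floor); calipers and oracle agree to 1e-9 on random
polygons.

Pixel geometry uses the **corner model**: each foreground pixel contributes
the four corners of its unit square, so an axis-aligned bar of w pixels
measures exactly w·spacing mm. On rasterized *rotated* shapes the corner
model is upward-biased by up to one pixel diagonal (|cosθ|+|sinθ| px);
this is the accepted discretization error bound. Measuring the minimum
width rather than a width perpendicular to an estimated long axis realizes
the same quantity without the axis-estimation step, and is
orientation-invariant by construction.

Multi-component masks are rejected in morphometry (cleanup is the
segmentation stage's single responsibility). CSA is pixel count × pixel
area. The bilateral mean divides by the number of *present* sides and flags
a missing side.

## Growth charts (LMS / BCCG)

Age-conditional reference distributions use the three-parameter Box-Cox
normal (BCCG) family — the classical LMS chart construction: L(t) the
Box-Cox power, M(t) the median in mm, S(t) the coefficient of variation,
with `z = ((y/M)^L − 1)/(L·S)` (log branch for |L| < 1e-8) standard
normal. The density includes the positive-support normalizer Φ(1/(|L|S)),
so it integrates to 1 exactly (tested by quadrature); centile conversions
use the plain `Φ(z)` form, whose truncation error is ≤ 2e-5 for the S
ranges involved.

**Fitting** maximizes the joint likelihood over B-spline coefficient
vectors for the three curves directly with L-BFGS-B and an analytic
gradient (including the normalizer terms). M and S use log links, L is
identity-linked and held constant (df 1) by default — a skewness curve is
poorly identified at moderate n. A curve with df k uses a degree
min(3, k−1) B-spline with k coefficients and interior knots at age
quantiles. The numeric-gradient alternative was observed to terminate
prematurely (tens of nats short of the optimum), which is why the analytic
gradient is not optional. Convergence: ftol 1e-12 on the penalized
objective; non-convergence raises with the optimizer trace.

**Model selection** minimizes BIC = −2·loglik + k·log n over a grid of
(df_M, df_S) candidates (default {2,3,4,5}²; k counts all coefficients).
Ages above 30 are collapsed to 30 before fitting — the upper tail is
sparse and an unconstrained spline end would whip. Ages are accepted in
[4, 35].

Chart statistics are defined explicitly because no canonical recipe
exists:

- `mm_per_centile`: mean over an integer-age grid and over adjacent
  centile pairs (α, α+1), α ∈ 1..98, of `y(α+1) − y(α)`.
- `centile_precision(mae)`: median over the age grid of
  `|centile(M(t) + mae) − 50|`, with a bootstrap 95% interval over ages.

Both depend on the fitted cohort's S and M, so their numeric values on
synthetic cohorts characterize *those cohorts*, not any clinical
population; the tests pin them only to closed forms on known-constant
models (e.g. precision = 100·(Φ(mae/(M·S)) − 0.5) for L = 1).

Leave-one-study-out refits the chart excluding each study block and
reports the maximum |ΔM(t)| in mm — a dominance check for multi-study
cohorts.

## Synthetic data

**Head phantoms** are ellipsoids (background 0, brain 100 with a smooth
deterministic ±25% in-plane modulation — a spike histogram would make any
threshold-based stage degenerate and is unlike real tissue) containing:
two lateral "temporalis" structures (intensity 160) built as shallow
annulus sectors whose sagitta is a fraction of a voxel, so the convex-hull
minimum width equals the requested thickness — *verified at build time*
against the angle-sweep oracle within half a voxel, with a rasterization
phase search, and an error if unrepresentable; a bright ridge (150) at the
landmark slice; and two wedge structures (135) whose disk radius varies
linearly with signed distance from the landmark, making the offset signal
learnable from MIPs. Gaussian blur (σ 0.5) and noise are applied *after*
truth extraction, so truth masks are exact at every noise level. A fixed
seed gives bit-identical volumes. Default grid 128×128×96 at 1 mm keeps
end-to-end tests in seconds.

What the phantom does **not** emulate: skull/CSF layers, bias fields,
partial-volume fat margins, pathology, or inter-subject anatomical
variability. Passing phantom recovery therefore validates the pipeline's
plumbing, geometry and contracts — not clinical segmentation accuracy.

**Cohorts** sample TMT from known per-sex L/M/S curves (default: L = 1,
M linear in age with a steeper male slope, S = 0.12 — magnitudes chosen to
match the single-cm scale and ~12% relative spread of reported temporalis
measurements), ages uniform, optional study blocks with additive M offsets
for LOSO. Parameter-recovery tests at n = 2000 bound M within 3% and S
within 15% of truth.

## Training problem sizes

Reference models train on 4 phantoms (slice regressor: 37 offsets per
phantom; segmenter: 3 slices per phantom, subsampled to ≤ 40k pixels per
image), chosen as the smallest family that exercises thickness, landmark
and noise variation; the overfit-sanity check uses 32 slices. These sizes
are the package's reference configuration for CPU training in well under a
minute each.

## Known limitations

- The slice regressor and segmenter are reference implementations for
  contract verification, not clinically trained models; published-scale
  architectures (DenseNet regressor, 5-level U-Net) would plug into the
  same contracts but are out of scope, as is rigid registration to age
  templates (inputs are assumed pre-aligned).
- The corner-model Feret is upward-biased up to one pixel diagonal on
  rotated rasterized shapes; at 1 mm spacing this bounds the TMT
  discretization error at ~0.7 mm per side in the worst orientation.
- BCCG only: BCT/BCPE (kurtosis-modelling) families are not implemented,
  so heavy-tailed cohorts will show PIT non-uniformity rather than being
  absorbed into a fourth curve.
- Binary-vote majority (not probability pooling) is used at tiles, per the
  strict-majority reading of the voting step; pooled probabilities would
  be a one-line change in `segment_muscles`.
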