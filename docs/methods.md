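# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limits of what the test suite can show.

## Encoding models

Spike counts to flashed images are modeled as a softplus function
r(F) = a₁ ln(1 + e^{a₂(F+a₃)}) of a scalar drive.  The LN drive is the
receptive-field-weighted mean Weber contrast I_mean over the pixels
inside the 3-sigma Mahalanobis contour of the fitted 2D Gaussian RF; the
SC drive adds the local spatial contrast, F_SC = I_mean + w·LSC, where
LSC is the sample SD (denominator N−1) of the same weighted pixel
values.  The RF kernel is peak-normalized (A=1, B=0): only relative
weights matter, and the printed normalization constant of a Gaussian
density is irrelevant after that choice.

a₁ and a₂ are kept positive via log-parameterization, so the
nonlinearity is monotonically increasing.  Polarity is therefore carried
by the sign of the drive: OFF cells are fit on −I_mean, consistent with
the STA sign convention used here (the spatial factor's peak is positive
and the temporal filter absorbs polarity).  LSC is sign-invariant, so
w > 0 means "spatial structure raises the count" for either polarity.

**Fitting.**  Least squares against trial-averaged counts on a 50/50
train/test split.  LN: Nelder–Mead simplex over (log a₁, log a₂, a₃)
with data-scaled random restarts (a₁ ~ max count, a₂ ~ k/SD(F),
a₃ ~ −median(F)).  SC: alternating optimization — simplex fit of the
nonlinearity with w fixed, then of w with the nonlinearity fixed — until
the relative residual change < 1e-8 or the parameter change < 1e-6, with
at most 500 alternations; the whole loop restarts from random initial
values (w ~ U(−2,2)) and keeps the best residual.  One restart always
starts at w = 0 so the LN solution's basin is explored; during a
smoothing-scale sweep each scale is additionally warm-started from the
neighboring scale's solution.  The default restart count is 200;
population-scale runs and the test suite use 3–20 restarts and cap
alternations at ~120, which reproduces the full fit to ~4 decimal
places at a fraction of the cost (the tail alternations change the
residual by ~1e-8 relative per step).

**Evaluation.**  R² is the squared Pearson correlation between predicted
and observed mean counts — affine-invariant, so a correlated but
miscalibrated prediction still scores high; this is deliberate and
documented because it diverges from 1−SSE/SST under miscalibration.
The prediction improvement is R²_SC / R²_LN on the same held-out set.

## Receptive-field estimation

STA over a 660-ms pre-spike window (20 frames at 30 Hz); spikes are
assigned to the last frame whose onset precedes them.  The (lags ×
pixels) unfolding is separated by SVD; both factors are unit-norm, with
signs chosen so the spatial peak is positive.  The 2D Gaussian fit
parameterizes Σ through its Cholesky factor (log diagonal) to stay
positive definite, is initialized from image moments, and runs through
Levenberg–Marquardt least squares; a negative-peak map is flipped and
flagged.  The effective diameter is √(a·b) with a, b the *full* axis
lengths of the 1.5-sigma contour (3√λ per principal axis) — the
full-axis reading makes d behave as a diameter (3σ for a circular RF)
and is applied identically to RFs, subunits and smoothing scales, so all
size comparisons are internally consistent.

## Synthetic study conditions

The generators define the conditions every population-level number in
this package is computed under:

- **Images** (300 per experiment): Gaussian random fields with 1/f
  amplitude spectrum on a 128-px grid at 7.5 µm/px (960 µm field),
  multiplied by a smooth lognormal contrast envelope (log-SD 0.8,
  correlation scale 240 µm), then standardized per image to zero-mean
  Weber contrast with SD 0.5 and clipped to [−1, 1].  The envelope is
  essential: a stationary Gaussian field with fixed per-image SD has
  nearly identical local contrast in every image (LSC coefficient of
  variation ≈ 0.08), which no natural ensemble has and which leaves a
  subunit cell indistinguishable from a linear one at population scale.
  With the envelope the LSC CoV is ≈ 0.5 and corr(|I_mean|, LSC) ≈ 0.5,
  the structure seen in real flashed-image data.  Setting
  `contrast_modulation=0` recovers the plain stationary field.
- **Cells**: linear cells use a circular Gaussian RF with σ = 100 µm
  (effective diameter 300 µm).  Subunit cells use σ = 130 µm (390 µm — a
  large cell, the class for which nonlinear integration matters most)
  pooling half-wave-rectified local averages: the polarity-signed
  contrast is low-pass filtered with a circular Gaussian of SD 20 µm
  (subunit 3-sigma extent 60 µm, the scale of bipolar RF centers),
  sampled on a square grid with spacing equal to the subunit SD inside
  the 3-sigma contour, rectified, and summed with RF-envelope weights
  normalized to sum to 1 (the normalization keeps the pooled drive on
  the I_mean scale regardless of subunit count).
- **Output stage**: softplus parameters are fixed per cell kind,
  calibrated once so trial-averaged counts span ≈ 0–20 spikes per
  300-ms window, the dynamic range of flashed-image recordings.
- **Trial noise**: counts are drawn from a mean-matched mixture of the
  adjacent-integer law (minimal-variance integer distribution) and a
  thinned binomial, hitting a target Fano factor of 0.3 exactly wherever
  an integer law of that mean can (below rate ≈ 0.7 the minimal-variance
  law is used alone).  Poisson and deterministic controls exist.  The
  sub-Poisson target of 0.3 matches the reliability scale of flashed-
  image recordings, but the mixture law itself is a stand-in: real data
  constrain the variance, not the full count distribution.
- **White-noise responses**: the checkerboard movie is filtered by the
  unit-norm RF kernel and a biphasic temporal filter (unit norm, gamma
  bumps; peak lag ≈ 2 frames, sign by polarity), the drive standardized
  to SD 0.04 — the typical spread of I_mean across flashed scenes, so
  the flash-calibrated softplus operates in its normal range — and
  spikes drawn as an inhomogeneous Poisson process per frame.

Under these conditions a subunit cell yields R²_LN ≈ 0.81,
R²_SC ≈ 0.96, corr(ΔLSC, ΔSpikes) ≈ 0.8 and w ≈ 0.2; a linear cell
yields improvement ≈ 1.00 and null correlations.

**What passing tests do and do not show.**  The generator reproduces
the second-order structure the analyses rely on (contrast statistics,
their coupling, sub-Poisson counts, subunit-scale nonlinearity) but not
phase structure of natural scenes (edges, objects), adaptation, temporal
within-flash dynamics, RF surrounds, or correlated noise across trials.
Recovery results therefore demonstrate correctness of the chain under
its own assumptions, not performance figures for any real retina.

## Paired-difference analysis

Images are stably sorted by I_mean (ties by image id) and adjacent
neighbors differenced (next − current), giving n−1 overlapping pairs;
ΔSpikes uses trial-mean counts.  Note a statistical subtlety: because
adjacent pairs share an image, the difference series are MA(1) with
lag-1 autocorrelation −0.5, which inflates the null sampling SD of
corr(ΔLSC, ΔSpikes) to √(1.5/n) ≈ 0.07 at n = 299 — null correlations
up to ±0.15 are unremarkable for single cells.  Under the low-noise
synthetic conditions the *residual* ΔI_mean dependence of an OFF linear
cell remains visible (corr ≈ −0.2 to −0.5 depending on seed); it
shrinks with image density and is far smaller than the raw
count-vs-I_mean dependence the pairing removes.

## Spatial-scale analysis

LSC is recomputed from images blurred with circular Gaussians (scale =
3× kernel SD; reflective boundary padding), I_mean always from the
originals; the SC model is refit per scale on a fixed split with a fixed
LN baseline.  The optimum is the vertex of the parabola through the R²
maximum and its two neighbors, accepted only as an interior estimate
(negative curvature, vertex inside the neighbor interval); otherwise the
boundary grid point is returned flagged, with no extrapolation.  Default
grid 0–195 µm in 15-µm steps; sweeps in tests use a 30-µm grid, which
the interpolation compensates for.

## Degenerate inputs and tie-breaks

Constant images cannot be standardized; constant spatial maps cannot be
fit; constant LSC makes w non-identifiable (the fit falls back to
LN-equivalent predictions, flagged); constant observed or predicted
vectors make the correlation undefined (error); all-zero counts give a
flagged degenerate fit with ≈0 predictions.  Counting windows are
half-open [start, end).  Zero denominators in polarity ratios count as
infinite ratios.  The odd/even reliability uses the symmetrized form
R²_sym = 1 − Σ(oᵢ−eᵢ)² / Σ[(oᵢ−m̄)² + (eᵢ−m̄)²] with m̄ the grand mean —
symmetric in the halves, 1 for identical halves, ≈0 for independent
noise.

## Limitations

- The SC model is phenomenological: w summarizes subunit nonlinearity
  but does not identify subunit layout or nonlinearity shape.
- Problem sizes in the test suite (image counts, seed panels, restart
  counts, scale grids) are chosen for desk-scale runs; the library
  defaults (200 restarts, 15-µm grid, 500 alternations) match the
  full-scale protocol.
- ON-OFF cells are excluded by design (non-monotonic contrast response);
  the mouse pipeline differs only in count window, polarity rule and
  inclusion thresholds.
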