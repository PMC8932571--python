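# rgcsc

Tools for testing whether retinal ganglion cells integrate visual space
linearly, built around a minimal phenomenological extension of the
linear-nonlinear (LN) encoding model for responses to flashed images.

## The problem and the model

A ganglion cell's spike count to a briefly flashed image is classically
predicted by the LN model: filter the image with the cell's receptive
field (RF), then apply a static output nonlinearity.  With the RF
summarized by a fitted 2D Gaussian G(**x**) (peak-normalized, A=1, B=0),
the LN drive is the mean weighted Weber contrast over the N pixels
inside the 3-sigma contour:

    F_LN = I_mean = (1/N) Σᵢ G(xᵢ) C(xᵢ)

Many ganglion cells, however, pool rectified subunits (bipolar-cell-like
inputs), which makes them sensitive to spatial *structure* inside the RF
that I_mean cannot see.  The spatial-contrast (SC) model captures this
with a single extra statistic — the local spatial contrast, the sample
standard deviation of the weighted pixel contrasts —

    LSC = sqrt( 1/(N−1) Σᵢ (G(xᵢ) C(xᵢ) − I_mean)² ),
    F_SC = I_mean + w · LSC

and one extra weight w.  Both drives pass through a softplus output
nonlinearity r(F) = a₁ ln(1 + e^{a₂(F + a₃)}), fit by least squares on
trial-averaged counts of a training image set (alternating optimization
of (a₁,a₂,a₃) and w for the SC model); performance is the squared
Pearson correlation R² on held-out images.

Around this core the package provides:

- **`rgcsc.synthetic`** — ground-truth generators: standardized
  natural-like images, binary checkerboard white noise, linear and
  rectified-subunit model cells, and calibrated sub-Poissonian spike
  counts, so the whole chain is testable without recordings.
- **`rgcsc.receptive_field`** — spike-triggered average, SVD separation
  into spatial and temporal factors, 2D Gaussian RF fitting, effective
  diameter (√(a·b) of the 1.5-sigma contour axes) and contour masks.
- **`rgcsc.image_features`** — Weber contrast, display-style image
  standardization, I_mean/LSC, and Gaussian smoothing at a spatial scale
  defined as 3× the kernel SD.
- **`rgcsc.encoding`** — softplus, LN/SC fitting, evaluation, splits.
- **`rgcsc.paired`** — the paired-difference analysis: order images by
  I_mean, difference adjacent neighbors, and correlate ΔSpikes with ΔLSC
  to isolate contrast effects from mean-intensity effects.
- **`rgcsc.spatial_scale`** — refit the SC model with LSC computed from
  smoothed images and interpolate the optimal smoothing scale, a proxy
  for subunit size.
- **`rgcsc.cell_metrics`** — spike counting, Fano factors, ON/OFF
  polarity classification (salamander and mouse variants), inclusion
  filters, odd/even reliability, and k-means functional clustering on
  (RF diameter, temporal-filter PC1).
- **`rgcsc.experiment`** — end-to-end orchestration over synthetic
  populations with per-stage seeding and a reproducibility manifest.

## Worked example

`examples/03_ln_vs_sc_models.py` simulates an OFF cell that pools
half-wave-rectified 60-µm subunits under a 390-µm receptive field,
computes I_mean and LSC for 300 natural-like images, fits both models on
150 training images and evaluates them on the 150 held-out ones:

```
$ python examples/03_ln_vs_sc_models.py
LN model: held-out R^2 = 0.731
SC model: held-out R^2 = 0.954  (w = 0.228)
prediction improvement R^2_SC / R^2_LN = 1.305
```

The LN model misses the variance driven by spatial structure; adding the
LSC term with a positive weight w recovers it.  For a spatially linear
cell the same script reports an improvement of ≈ 1.00 and w ≈ 0.
The other scripts in `examples/` walk through RF recovery from white
noise, the image statistics, the paired-difference analysis, the
smoothing-scale sweep and a small population experiment; each prints a
line explaining what its numbers mean.  A thin CLI (`rgcsc --help`)
exposes the same steps for file-based workflows.

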