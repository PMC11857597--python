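# Methods

`microspot` re-implements the onboard analysis of a low-cost fluorescence
microarray reader for multiplexed serum biomarker panels (the motivating
application is a five-analyte lupus-nephritis panel: VSIG4, OPN, VCAM1,
ALCAM, TNFRSF1B, printed in triplicate alongside BSA-biotin positive and
PBS negative controls). This note records the models, the parameters that
matter, the numerical conventions, and what the synthetic-data experiments
do and do not demonstrate.

## Spot calling

One well is imaged as one 8-bit RGB frame; Cy3 emission is carried almost
entirely by the red channel, which becomes the analysis raster. The
detection chain is:

1. **Gaussian smoothing** — convolution with a normalized, truncated 9×9
   Gaussian kernel (reflective borders). The kernel width defaults to the
   common size-derived rule σ = 0.3·((k−1)/2 − 1) + 0.8 ≈ 1.7 px for k = 9;
   both k and σ are parameters.
2. **Global intensity thresholding** on the smoothed frame. Printed spots
   are sparse bright blobs on a dark background, so the default threshold
   is mean + 3·std of the smoothed frame; Otsu-style bimodal methods are
   deliberately avoided because fluorescence frames with few bright spots
   are not bimodal. Absolute and percentile thresholds are selectable.
   The mask is strict (`> threshold`), so a perfectly flat frame produces
   no detections.
3. **Connected components** (8-connectivity by default) with per-component
   area, perimeter, unweighted-centroid, circularity 4πA/P², and raw-frame
   mean intensity.
4. **Filtering** — keep components with area ≥ 100 px (inclusive; the
   cutoff reflects the minimum credible spot size, and sub-cutoff debris
   such as dust is discarded) and circularity ≥ 0.6.

## Grid anchoring and the bounded search rule

The dispenser prints spots at declared coordinates, so localization is
anchoring, not discovery. Detected contours are assigned to the luminous
(positive) control labels by minimum-total-distance one-to-one assignment
(Hungarian algorithm); PBS negative controls carry no fluorophore and are
never expected in the mask — they are measured later at their mapped
positions. A similarity transform (translation + isotropic scale; rotation
available but off by default, since slide seating dominates variation) is
fit by least squares on the assigned pairs and rejected if the RMS
residual exceeds a tolerance (default 25 px).

Test-spot positions are the transformed layout positions, accepted only
inside the admissible region: within the search range of the anchor-row
axis (1200 px at the 4056-px reference sensor width, rescaled by the
actual frame width — ≈303 px at the default 1024×768), and within the
x-segment bounded by the two bound controls (C4, C7), both inclusive.
Labels mapping outside are flagged `missing`.

## Quantification

Each spot is measured over a fixed disc at the ROI center (radius =
declared spot radius × fitted scale, 2·σ_spot in the default geometry).
The detected contour, when present, refines the ROI center but is *not*
the default measurement footprint: a threshold-dependent contour covers
only the bright core of a Gaussian spot and biases the mean high by
10–15% in a way that depends on amplitude; a fixed disc makes intensities
comparable across spots and against ground truth. Contour-restricted
averaging remains available (`use_contour_mean=True`).

Background is the median of a square annulus 6–14 px beyond the ROI,
excluding pixels of any neighboring ROI. The margins put the annulus at
≈3σ–4.3σ from the spot center, where the Gaussian tail is negligible;
tighter margins (e.g. 2–8 px) leak 1–2% of the peak into the background
estimate. Net intensity = disc mean − background, exactly. SNR = net /
annulus standard deviation; on a noise-free annulus any positive net is
reported as infinite SNR rather than zero. Flags: `saturated` (any member
pixel at 255), `low_snr` (SNR below 3; not applied to negative controls,
whose blankness is nominal), `missing`, `clipped`.

## Replicates, normalization, calibration

Triplicate nets are averaged over usable replicates (those not flagged
missing/saturated); the reported CV uses the population (ddof = 0)
standard deviation, the convention appropriate when the three printed
replicates are the entire population of interest. Normalization divides
the analyte mean net by the same well's positive-control mean net,
cancelling global illumination/exposure gain (verified on synthetic wells
rendered at 2× gain ratios).

Calibration is the four-parameter logistic y(x) = d + (a−d)/(1+(x/c)^b),
fit by unweighted least squares (1/y² weighting optional) with a fixed
deterministic initialization: a = min(y), d = max(y), c = geometric mean
of the nonzero standards, b = 1. Flat data returns a degenerate curve
with r² = 1 by the SS_tot = 0 convention. Concentrations come from the
closed-form inverse x = c·((a−y)/(y−d))^(1/b), defined only strictly
between the asymptotes; out-of-range intensities yield no concentration
rather than an error. The simulated standard series defaults to 7 points,
3-fold dilution, triplicate, with the top chosen so the series brackets
the inflection concentration symmetrically on the log scale
(top = c·fold^((n−1)/2)) — the usual immunoassay design; a series parked
on the upper plateau wastes standards and degrades the relative fit.

## Panel statistics

Group comparison is Welch's two-sided t-test. AUC is the Mann–Whitney
pair-counting probability (ties 0.5) that a case outscores a control,
with a 95% CI from DeLong's structural-components variance (implemented
here and cross-validated against R pROC's `ci.auc(method="delong")`).
The combined panel score defaults to the mean of per-analyte
rank-standardized values — monotone-invariant and parameter-free; an
in-sample logistic combination is available. Both are stated as
interpretations: the combination rule behind published "overall" panel
scores is generally not specified. No multiplicity correction is applied
by default; Benjamini–Hochberg is available.

GenePix result tables (GPR, ATF 1.0 dialect) are parsed for
cross-platform comparisons: foreground/background medians at 532 nm plus
a derived net column.

## Synthetic scenes and cohorts

The renderer emulates one well: isotropic Gaussian spots (σ = 6 px by
default; the reader's true point-spread is not modeled) at the layout
positions, a background plane (level 20, optional gradient), additive
Gaussian read noise, optional hard-disc dust artifacts below the area
cutoff, 8-bit round-half-up quantization with saturation tracked in the
ground truth. The default frame is 1024×768 — a desk-scale stand-in for
the 4056×3040 sensor that preserves the geometry ratios (rows 80 px
apart, all inside the rescaled search band). Ground truth records, per
spot, the noiseless signal+background mean over the footprint disc of
radius 2σ, so measured net intensities are directly comparable.
Default amplitudes: positive controls 200, test analytes a 5-step ladder
100–200 on background 20, keeping a +20 background shift below the 8-bit
ceiling.

Designed cohorts draw per-sample analyte amplitudes from the binormal
equal-variance model: class shift δ = √2·Φ⁻¹(AUC) pins each analyte's
design AUC (defaults 0.95/0.95/0.90/0.80/0.90 across the five analytes;
baseline 120, SD 20, per-replicate jitter SD 3). Each of the 10 + 10
samples is rendered as a full well (seeded noise, seeded slide shift up
to ±15 px) and pushed through the complete calling/normalization chain.

What these simulations do **not** show: real spot morphology (comet
tails, donuts, merged spots), spatially correlated illumination fields,
autofluorescent serum background, pixel-response non-uniformity, or
clinical between-subject covariance between analytes. Passing synthetic
recovery tests demonstrates the algorithmic chain is correct and
well-calibrated, not that the panel's clinical numbers transfer.

## Known limitations and numerical notes

- DeLong intervals degenerate to [1, 1] whenever the empirical AUC is
  exactly 1, which at 10 vs 10 samples happens with probability ≈0.19 for
  a design AUC of 0.95; small-cohort CI coverage of the design value is
  therefore intrinsically below nominal (≈0.72 at 0.95). This is a
  property of the estimator, not of the pipeline.
- The 4PL zero-dose asymptote *a* is unidentifiable when its magnitude is
  far below the dynamic range times the noise CV; recovery statements
  pool parameters.
- The inverse/forward 4PL round trip is exact to ~1e-12 for slopes in the
  physiological range (b ≈ 0.5–2.5); for extreme slopes the limit is
  double rounding of y near the asymptotes, not the algebra.
- Problem sizes used throughout the test-suite experiments: 20 wells for
  spot-calling recovery, 10 wells for quantification fidelity, 50
  simulated standard curves, 20 image-based cohorts of 20 samples.
- Watershed splitting of merged spots, flat-field correction, 5PL
  models, and LOD/LOQ estimation are out of scope.
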