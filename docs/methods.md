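# Methods

## The score

The pancreatic margin score of a border fragment is the root-mean-square
deviation of the detected border from a smooth "average boundary line"
fitted through it, in pixels. The model separates border geometry into three
scales:

* **organ scale** (wavelengths ≳ 4 × knot spacing): curvature of the gland
  itself — absorbed by the baseline spline, not counted as irregularity;
* **nodularity scale** (≈ 4 px to ≈ knot spacing): the lobulation signal
  the score is designed to measure — left in the residuals;
* **sub-pixel scale**: unresolvable; contributes a quantization floor.

The measurement assumes the border fragment inside the box is an open,
roughly single-valued curve (a margin, not a closed lesion contour); borders
that fold back over their principal axis are rejected explicitly rather than
scored incorrectly.

## Pipeline and parameters

| parameter | default | units | role |
|---|---|---|---|
| ROI size | 40 × 40 | px | constant across a study (paired design) |
| Canny σ | 1.0 | px | detection scale |
| high threshold | 0.90 quantile | — | of the ROI's nonzero gradient magnitudes |
| low threshold | 0.4 × high | — | hysteresis linking |
| knot spacing | ROI width / 4 | px | baseline stiffness — the critical free parameter |
| threshold | 0.6855 | px | published single-center classification cutoff |

Quantile thresholds make the edge map exactly invariant under affine
intensity rescaling, so the detector needs no knowledge of the scanner's
intensity calibration. Knot spacing is the one parameter that changes what
"irregularity" means: smaller values let the baseline follow (and thus hide)
coarse nodularity. Every result carries a fingerprint hash of all
score-influencing parameters; equal fingerprints guarantee comparable scores.

Edge coordinates are integer pixel centers. This matches the whole-pixel
units of the published score and implies a quantization floor of
1/√12 ≈ 0.289 px on the RMS residual; measured floors across orientations
are ≤ 0.25 px because the spline absorbs part of the staircase pattern. An
optional quadratic sub-pixel refinement exists behind a flag (off by
default). The classification threshold is shipped as the published
single-center, single-scanner value and should be recalibrated per protocol;
scores are reported in pixels, with millimeters added only when the source
DICOM carries (isotropic) pixel spacing.

Numerical details: non-maximum-suppression ties (symmetric step edges whose
true border falls exactly between two pixels) are broken toward the darker
pixel, a rule that is covariant under rotations and monotone intensity maps;
border selection ties prefer the lexicographically smallest pixel, and the
extracted path runs from its lexicographically smaller endpoint, so the
whole chain is deterministic. When a border carries fewer points than the
spline has coefficients, interior knots are removed until the least-squares
problem is solvable, and the count used is recorded.

## The phantom generator

Phantoms emulate exactly one thing: a two-phase parenchyma/fat step edge of
known geometry, observed through a CT-like measurement chain. The border is
a base curve (straight line at any angle, or circular arc, optionally with a
long-wavelength organ-scale bend) plus a roughness perturbation: a sum of 12
sinusoids with wavelengths drawn uniformly from a band (default 4–12 px) and
uniform phases, rescaled so the realized RMS about the base curve equals the
requested amplitude exactly. The step is rasterized with per-pixel area
coverage (4 × 4 subsampling), blurred with a Gaussian PSF (default σ = 1 px)
and degraded with additive Gaussian noise (default σ = 2 gray levels at a
90-level contrast); ground truth is recorded before degradation. Default
contrast is 110 (parenchyma) over 20 (fat) on an 8-bit-like scale — the
ordering, not the HU values, is what matters.

What phantoms do *not* model: real organ shapes, partial-volume effects of
oblique slices, structured reconstruction noise, neighboring organs or
vessels touching the border, and reader variability in box placement.
Passing phantom tests therefore demonstrates that the *measurement chain* is
correct and calibrated on band-limited roughness — not that the published
clinical numbers transfer to any particular scanner.

A simulated paired cohort assigns patient *i* the seed *base + i* in both
arms, so single pairs can be regenerated; the smooth (tumor-like) and rough
(healthy-like) arms of one patient share a seed and differ only in
amplitude. On disk, each patient's two phantoms are composited side by side
into one 16-bit PNG with the two constant-size boxes recorded in the
manifest.

## Validation protocols and what they show

All protocols live in `pancedge.validation` and are deliberately sized to
run in seconds-to-minutes on one CPU (20 phantoms per amplitude on a
176 × 176 image; a 50-pair cohort on 64 × 64 images).

* **Quantization floor** — noise-free smooth borders at 0°–90° score
  ≤ 0.25 px, confirming integer-pixel placement is the only residual source.
* **Roughness recovery** — median score increases strictly with true RMS
  amplitude over {0.5, 1, 2, 4} px. Recovery is quantitatively accurate for
  roughness wavelengths comfortably above the detection scale (median
  relative error ≈ 15–20% for a 10–20 px band) but biased low in the 4–12 px
  default band: the detected edge is the ridge of a blurred gradient field,
  so border position is effectively low-pass filtered with
  σ ≈ √(blur² + Canny σ²) ≈ 1.4 px, attenuating a wavelength-λ component by
  ≈ exp(−2π²σ²/λ²) — 0.54 at λ = 8 px, 0.09 at λ = 4 px. At 1 px amplitude
  the measured median error is ≈ 40%; large amplitudes fare better (≈ 14% at
  4 px RMS) because ridge-following is nonlinear in amplitude. Reducing the
  detection σ does not help: the phantom's own PSF dominates, and finer
  scales fragment the border instead. **This attenuation is an inherent
  limitation of edge-based roughness scoring near the PSF scale, and the
  reason the score should be read as a relative index, not an unbiased
  roughness estimate.** At 4 px RMS the blur can erase the gradient at sharp
  excursion tips entirely, fragmenting the border; unscorable phantoms are
  counted and excluded, the same way an unusable clinical box would be
  re-drawn.
* **Cohort replica** — a 50-pair smooth (0.5 px) vs rough (1.5 px) cohort
  yields paired *t* ≈ −18 (p ≪ 0.001), AUROC ≈ 0.99–1.0, and a Youden
  threshold strictly between the group medians with sensitivity and
  specificity ≥ 0.9 — the qualitative structure of the clinical result,
  at the package's own effect sizes.
* **Invariances** — edge maps are bit-identical under affine intensity maps;
  scores change ≤ 5% under exact 90° rotation; adding an organ-scale bend
  (wavelength 4 × knot spacing, amplitude 5 px) shifts the median score by
  ≤ 10% (medians over 12 phantoms are compared, because the bend re-samples
  the border against the pixel grid and re-rolls per-phantom quantization
  noise of up to ±18%, which would otherwise be mistaken for baseline
  leakage).

## Design choices made where the design was open

* **Baseline form**: a least-squares cubic spline (continuous first
  derivative, linear-in-coefficients, reproduces straight lines exactly);
  stiffness expressed as knot spacing rather than a smoothing penalty so the
  absorbed wavelength scale is explicit.
* **Residual direction**: perpendicular to the principal axis, not to the
  local fitted curve — a 1D regression framing that differs from true
  normal distance by O(slope²); adequate for borders roughly aligned with
  their box, and the reason strongly hooked borders are rejected instead.
* **Border choice among multiple edges**: largest component + geodesic
  between farthest pixels. Deterministic and parameter-free; can clip side
  branches of a genuinely branching edge (counted into the score only via
  the points actually on the path).
* **Fold-over rule**: a path step counts as a fold when it moves > 0.5 px
  backward along the axis; steep but single-valued borders take
  near-perpendicular steps with axis components near zero, which a strict
  sign test would miscount. Tolerance: 10% of steps.
* **Positive class and direction**: cancer is predicted by *low* scores, and
  a score equal to the threshold is called healthy.
* **Paired arms share per-patient seeds**: arm differences then reflect the
  amplitude difference alone, which sharpens the paired design; independent
  noise realizations would only add variance.

## Known limitations

* Systematic underestimation of roughness at wavelengths ≲ 6 × PSF σ (see
  above); the score is a relative, protocol-calibrated index.
* Pixel-unit scores are resolution-dependent; thresholds do not transfer
  across reconstruction settings unless converted to millimeters via pixel
  spacing.
* Single-slice, single-box scoring: no aggregation over slices or readers.
* The statistics layer reports no confidence interval for the AUROC.
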