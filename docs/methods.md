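# Methods

## Optical model and deconvolution

A brightfield pixel transmits `I_c = I0_c · 10^(−OD_c)` per RGB channel,
so `OD_c = −log10(I_c / I0_c)` is additive over co-localised absorbers.
With unit stain colour vectors `v_H` (haematoxylin) and `v_DAB` stacked
with an orthogonal residual row into a 3×3 matrix `M`, a pixel's OD
vector is `od = c · M` and the stain concentrations are `c = od · M⁻¹`,
in OD units along each stain vector.

Choices and their reasons:

* **Stain basis.** The default is the published Ruifrok–Johnston H-DAB
  basis, haematoxylin ∝ (0.650, 0.704, 0.286) and DAB ∝ (0.269, 0.570,
  0.776), unit-normalised, with the residual row as their normalised
  cross product (so pure two-stain mixtures have zero residual and the
  matrix is always invertible). The basis is configurable as nine floats;
  automatic estimation (Macenko-style) is deliberately out of scope.
* **White reference.** `I0 = 255` per channel by default; overridable.
  No blank-field correction is attempted.
* **Zero intensities** are clamped to 1 before the log, bounding OD at
  `−log10(1/255) ≈ 2.4065`. Intensities above `I0` clamp to OD 0.
* **Negative concentrations** (noise below the white point) are clamped
  to 0 for scoring (`clamp=True`), because they would otherwise leak into
  the %Pos denominator; the raw unclamped solution is the default return
  so the linear round trip stays exact.
* **Quantisation budget.** 8-bit intensities quantise OD with step
  `≈ 0.5/(I·ln10)`; after unmixing, per-pixel recovery is within 0.01 OD
  for stain concentrations up to ≈ 0.6. Denser stains are still measured
  accurately as *region means* because realistic sensor noise (applied
  before the ADC rounds to 8 bits) dithers the quantisation — with the
  default noise of 1 grey level, region-mean DAB recovery stays within
  0.01 OD across the whole 0–2 OD range. Measurement of dense stain from
  a single noiseless pixel is fundamentally quantisation-limited and no
  algorithm can do better at 8 bits.

## Grey encoding and step-tablet calibration

Concentration maps are re-encoded for thresholding as
`grey = round(255·10^(−c))` (no stain = white = 255). The step tablet
maps grey back to OD by piecewise-linear interpolation between monotone
(grey, OD) knots, clamping outside the knot range. Linear interpolation
was chosen over ImageJ's Rodbard sigmoid because it is parameter-free and
exactly testable; a laboratory's own tablet can be dropped in as a
two-column CSV.

The packaged default tablet is synthetic: knots at
`grey = round(255·10^(−od))` for OD 0.0–2.0 in 0.1 steps, which makes the
calibration the exact inverse of the grey encoding at the knots. At the
dark end the 8-bit grid collapses OD 1.9 and 2.0 onto grey 3; duplicates
keep the denser value, so the tablet has 20 knots. Grey→OD→grey round
trips are exact at knots, within 0.01 OD below ≈ 0.9 OD, and degrade with
the grey grid above that (half a grey level at grey g is `0.217/g` OD).

## ROI scoring

ROIs are simple polygons in 0-based pixel coordinates (x right, y down),
validated as non-self-intersecting. A pixel belongs to the mask iff its
centre (x+0.5, y+0.5) lies inside any polygon (even-odd rule; the union
over polygons). Pixel-centre rasterisation makes counts exact: an
axis-aligned w×h rectangle with integer corners selects exactly w·h
pixels. Polygons wholly outside the image warn and contribute nothing;
an empty union is an error, never a silent zero.

Positivity uses the DAB-deconvolved 8-bit grey with the window
[t_min, t_max] = [67, 206], bounds inclusive: grey above 206 is unstained
background, below 67 over-saturated pigment or artefact. In OD terms the
window is ≈ [0.093, 0.580]. Mean OD is computed over **all** masked
pixels (not positive pixels only), and on the DAB channel only — the
antibody signal is the quantity of interest, and the counterstain must
not contribute. The composite per-sample value is
`score = mean OD × %Pos`, an intensive quantity: duplicating a stained
region leaves it unchanged, and adding in-window stained pixels can only
raise it.

## Statistics

* **Kruskal–Wallis** on midranks with tie correction
  `H' = H / (1 − Σ(t³−t)/(N³−N))`, p from χ² with k−1 df; per-class mean
  midranks are reported because group-level reporting in this field is
  rank-based. All-identical data defines H = 0, p = 1.
* **Pairwise Wilcoxon rank-sum**, two-sided, per class pair. The p-value
  is exact when the pooled sample is untied and both groups have n < 50
  (matching R's `wilcox.test`, the reference behaviour for this
  analysis), otherwise a tie-corrected normal approximation with
  continuity correction. The reported W is the smaller rank sum.
  Adjustment across pairs is Benjamini–Hochberg step-up by default
  (controls the false discovery rate); Bonferroni is available.
* **ROC/AUC.** Operating points at every midpoint between distinct
  scores plus ±∞, direction fixed as higher score ⇒ diseased (no
  auto-flip). The AUC is computed as the Mann–Whitney pair statistic
  (ties ½), which equals the trapezoidal area under the curve. The 95%
  CI is DeLong's variance by default, or a seeded percentile bootstrap
  (2000 resamples); both truncate to [0, 1] and always contain the point
  estimate.
* **Youden index** J = sensitivity + specificity − 1, maximised over all
  operating points with ties broken toward the lowest threshold so a
  single cut-off can be quoted.
* **Logistic combination** of the two markers: unpenalised ML via
  Newton/IRLS (step tolerance 1e−10, ≤ 100 iterations); at convergence
  the score equations hold to 1e−8 in max norm (verified against
  statsmodels in the tests). Complete separation is detected (perfect
  in-sample prediction with diverging coefficients) and flagged; the
  returned probabilities still rank the samples. Constant markers are
  dropped with coefficient 0, so the combination degrades gracefully to
  the informative marker. Collinear designs fall back to least-squares
  Newton steps rather than failing.
* **Sample size** for two proportions with unequal allocation κ =
  n_large/n_small (Rosner form): with pooled `p̄ = (p₂ + κp₁)/(1+κ)`,

      n_small = [ z₁₋α/₂ √(p̄q̄(1+1/κ)) + z₁₋β √(p₂q₂ + p₁q₁/κ) ]² / (p₁−p₂)²

  and `n_large = κ·n_small`, rounded to the **nearest** integer (ceiling
  available as an option). At p₁ = 0.8, p₂ = 0.2, α = 0.05, power 0.8,
  κ = 10 the raw values are 43.30 and 4.33, giving (43, 4).

## Synthetic data

The phantom generator forward-renders the same optical model the
deconvolution inverts: haematoxylin discs (random non-overlapping nuclei,
OD 0.4–0.8, radius 3–6 px by default), rectangular DAB regions with exact
pixel counts, rectangular zero-stain "excluded" regions standing in for
necrosis/lumen (precedence excluded > nucleus > stained), Gaussian sensor
noise of σ = 1 grey level added to the continuous intensity before the
single 8-bit rounding, all driven by one seed. Ground-truth OD maps and
the label partition are returned with the image; at σ = 0 the render is
exactly `round(I0·10^(−c·M))`.

The score simulator draws per-class log-normal scores — non-negative,
right-skewed, as composite OD×%Pos products are. Because AUC between two
log-normal groups depends only on the latent normals,
`AUC = Φ(δ/√(σ₀²+σ₁²))`, a target AUC translates into a location shift
(`lognormal_shift_for_auc`). Defaults: control n=16 (log-mean ln 5,
log-sd 0.6), HCC n=48 (shift 1.396 ⇒ binormal AUC 0.95 vs control), CCA
n=8 (≈ control), metastases n=24 (intermediate, overlapping HCC) — a
cohort-scale rendering of the qualitative pattern expected of this
marker family (HCC high; control and CCA low; metastases in between),
with the ~10:1 tumour-to-control skew of archival material. These are
defaults of the generator, not estimates fitted to any dataset.

What passing on phantoms shows — and does not. Phantoms prove the
algebra: unmixing, calibration, masking, thresholds and statistics are
exactly as specified, and recovery is quantisation-bounded. They do not
contain real histology texture, uneven illumination, stain gradients or
out-of-basis pigments, so performance on real slides additionally
depends on staining and scanning quality and on ROI placement, which
remains the analyst's responsibility.

## Problem sizes and numerical choices

The validation suite uses 100 phantoms of 256×256 for round-trip
recovery, 1000 random small instances for oracle equivalence of the rank
and ROC statistics, 2000 replicates of n = 30 per group for type-I
calibration, and 500 samples per class for designed-AUC recovery —
sizes at which the sampling bands quoted in the tests are tight while a
full run stays fast on a laptop. Ties in Youden break low, ROC direction
is fixed, bootstrap CIs are seeded, and all simulation randomness flows
from explicit integer seeds, so identical configurations reproduce
byte-identical outputs.

## Known limitations

* 8-bit quantisation bounds single-pixel OD accuracy (see above); 16-bit
  input is rejected rather than silently truncated.
* The positivity window is a fixed grey interval; it is the user's
  calibration responsibility if a different scanner/stain combination
  shifts the DAB grey distribution.
* The pairwise exact/asymptotic switch follows R's convention; exact
  p-values with heavy ties are not attempted (the tie-corrected normal
  approximation is used instead).
* DeLong CIs assume independent samples; clustered cores from the same
  patient would need a clustered variance, which is not implemented.
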