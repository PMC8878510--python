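# Methods

## Segmentation model

The DAPI channel is treated as an 8-bit raster normalized to [0, 1]
(division by 255). Background is estimated as the running minimum over a
square window (default 50 px per side) and subtracted; this preserves
compact bright objects smaller than the window (nuclei are 10–200 px² here)
while flattening slowly varying background. The choice of a *subtractive*
background correction matters: applying a 50-px minimum filter directly to
the signal would erase every nucleus below the window size, contradicting
the downstream 10/200-px area thresholds, so the filter is read as a
background estimator.

The subtracted image is saturated to its 5th and 95th percentiles (linear
interpolation between order statistics) and rescaled so P5 → 0, P95 → 1.
When the two percentiles coincide, the limiting step rule applies: values
above the common percentile map to 1, the rest to 0. This is the pointwise
limit of the clipped affine rescale as P95 → P5 and reduces to an all-zero
output on constant rasters. The binary nucleus mask is `value > 0.4`
(strict: a pixel at exactly 0.4 is background), debris below 10 px² is
removed (the optional `max_single_area` knob can additionally cull very
large objects; it is off by default because over-large objects are routed
to splitting instead), and components above 200 px² enter the splitting
routine.

**Splitting.** Touching nuclei are separated by a marker-controlled
watershed. Seeds are maxima of the component's Euclidean distance transform
detected with an h-maxima transform (prominence h = 1 px) and merged when
closer than 3 px. Prominence-based detection is deliberate: the discrete
EDT of a single elongated convex nucleus carries several shallow maxima
along its ridge, and plain local-maximum detection fragments such nuclei,
while genuinely bimodal touching pairs have deep saddles and keep two
seeds. The flooding surface is −(EDT × saturated DAPI), so both geometry
and signal shape the cut. Splitting is masked to the component: it never
adds or removes foreground pixels.

## Nucleus classification

Three features per nucleus: area (pixel count), eccentricity of the
moment-equivalent ellipse, and k-3 density — the mean centroid distance to
the 3 nearest other nuclei (NaN, never fabricated, when fewer than 4 nuclei
exist; at prediction time a missing feature is imputed at the training mean,
which removes its contribution from the affine scores). Features are
z-scored (area ~10² px² and eccentricity ~1 are incommensurate) and fed to
a multinomial logistic regression; prediction is the argmax of affine
scores, so any trained model is a plain linear rule and serializes to a
versioned JSON document with weights, standardization parameters and a
training-table fingerprint.

Three classes are kept: `human`, `chicken_peripheral` (the CAM rim) and
`chicken_infiltrating`. `exclude_cam` removes only the rim class from the
record set (as a view — nothing is deleted); infiltrating chicken cells stay
flagged and are excluded from human metrics by per-class aggregation. The
shipped `default_model()` trains on the separable feature preset
(human: A ~ N(120, 15²), e ~ N(0.30, 0.05²); chicken: A ~ N(35, 8²),
e ~ N(0.85, 0.05²); rim k3 ~ N(6, 1.5²) vs infiltrating k3 ~ N(28, 4²)).
Note that k-3 density scales with nuclear packing density, which varies
with magnification and tissue: for real use (and for rendered scenes),
train on feature tables from matching images —
`training_features_from_truth` produces one from any synthetic scene.

## Marker quantification

Cytoplasm is indexed to nuclei by Euclidean-distance label expansion: every
background pixel within `expansion_radius` (default 10 px) of a nucleus
takes the nearest nucleus's label. Equidistant pixels are resolved
deterministically by the distance transform; territory boundaries land on
the perpendicular bisector to within 1 px of digitization.

Marker masks use the same normalize → background-subtract → 0.4-threshold
chain as DAPI but are **not** percentile-saturated. Per-cell MFI is the
mean of the nuclear-region mean and the cytoplasmic-region mean
("mean of region means"; a pooled-pixel mean is available via
`combine="pooled"`). A cell with no cytoplasmic pixels reports a missing
cytoplasmic MFI and falls back to its nuclear mean. Positivity: a cell is
positive when |cell region ∩ marker mask| > 5 px, strict, where the cell
region is the nucleus plus its territory.

**Elongation filter.** For fibrous markers the mask is first filtered to
components with area > 20 px and perimeter/area > 0.5. The ratio threshold
is estimator-dependent, so the perimeter estimator is pinned: the
4-connected boundary-step count (a 2×30 rectangle scores 2·(2+30) = 64,
ratio 1.07; a radius-10 disk scores ≈ 84 over ≈ 317 px, ratio ≈ 0.26). A
Crofton estimate is available as an alternative but is not the default.
Slide summaries report per-class mean MFI over all cells of the class and
over positive cells only (both, since the aggregation base is a modelling
choice), positive counts, and double-positive percentages whose denominator
is the first marker's positive human cells; empty denominators are reported
missing, not zero.

## IHC scoring

DAB staining is scored on the optical-density sum
OD = Σ_channels −log10(max(I, 1)/255) (intensities floored at 1 keep OD
finite; pure white is exactly 0). Cells are positive at mean OD ≥ 0.1 and
binned left-closed at 0.2/0.4/0.6 into 1+/2+/3+; a positive cell below 0.2
is reported in the lowest bin with a logged note. The module reuses this
package's segmentation and region machinery and applies only these
printed thresholds; it does not reimplement any external positive-cell
detector (background radius, smoothing sigma, cell expansion), so its
scores are comparable in structure, not bit-exact, to such tools. The 0.1
threshold is applied to the mean (not maximum) cellular OD.

## Relative expression

ΔCq normalizes the target's replicate-mean Cq against the arithmetic mean
of the two housekeeping replicate means (equivalent to geometric-mean
normalization of quantities); ΔΔCq is the treated-minus-control difference
of group mean ΔCq, and fold = E^(−ΔΔCq) with amplification efficiency E = 2
(the classic assumption; exposed as a parameter). p comes from a two-sided
Welch t-test on per-sample ΔCq; singleton groups yield a fold but a missing
p. The dual cut-off flags a gene only when |log2 fold| > 1 AND p < 0.05,
both strict; down-regulation is treated symmetrically (fold < 0.5 passes
the magnitude clause). No multiple-testing correction is applied.

## Synthetic scenes

Nuclei are filled ellipses (orientation uniform in [0, π)), which realize
any target area/eccentricity exactly up to rasterization; the ground-truth
table records the realized pixel count and moment eccentricity. Human
nuclei are placed in the interior, CAM-rim chicken nuclei in a border
annulus (`rim_width`, default 40 px) — giving the k-3 feature real signal —
and infiltrating chicken nuclei uniformly in the interior. Placement is
rejection sampling with a clearance rule (boundary gap ≥ 3 px, so
ground-truth counts are exact under 8-connected labeling); bounded retries,
then an explicit error naming the class that did not fit.

Touching pairs (for the splitting routine) are near-circular ellipse pairs
of ≥ 115 px² each at centre distance 0.85·(r₁+r₂), which makes the union
exceed 200 px² and the distance transform bimodal by construction. Markers:
`cytoplasmic_ring` paints the whole cell territory (nucleus + ring out to
`marker_radius`, default 10 px, matching the quantification expansion
radius) so a noise-free positive cell's nuclear, cytoplasmic and combined
MFI all equal the specified intensity to within 1/255; `elongated_fibre`
paints a 2×30 px rectangle (aspect 15) through the cell, which passes the
elongation filter by construction. When markers are present, marker-target
cells keep a 2·marker_radius + 2 px clearance so rendered signal never
bleeds into a neighbour's territory — positive counts are then exactly
recoverable. Noise is additive Gaussian (default sd 0.02 of full scale)
clipped to [0, 1]; quantization is round-half-up to uint8. One seeded
generator drives all randomness, so identical parameters give bit-identical
scenes.

**Scene geometry and what passing tests show.** The default field is
512×512 px with ~8% nuclear coverage, the regime the percentile saturation
presumes: with tissue-scale density the 95th percentile lands inside the
nuclear intensity and the 0.4 threshold separates signal from noise. On a
sparse field (≈2% coverage) both percentiles fall in the background and
the fixed 0.4 threshold is not meaningful — the recovery results therefore
speak to tissue-like densities, not to sparse cell-culture fields. The
generator also omits optics (no PSF, vignetting or autofluorescence), so
passing tests validate the measurement logic, not robustness to real
microscopy artefacts. Runtime checks use a density-matched 1024×1024 scene
(800 nuclei).

## Numerical choices and degenerate inputs

- Percentiles: numpy linear interpolation between order statistics.
- Thresholds at 0.4 and the 5-px overlap are strict (`>`); IHC positivity
  (≥ 0.1) and bin edges are left-closed, matching intensity-threshold
  semantics.
- 8-bit quantization is round-half-up after clipping.
- Empty scenes, empty record lists, empty cytoplasm, empty double-positive
  denominators and sub-4-nucleus k-3 all return flagged/missing values or
  empty outputs, never fabricated numbers.
- Classifier ties (equal affine scores) resolve to the first class in the
  model's class order; k-nearest ties are irrelevant to k-3 because only
  distances, not neighbour identities, enter the mean.
- All pipeline constants live in `camquant.pipeline.PIPELINE_DEFAULTS` and
  are echoed into every run manifest.

## Known limitations

- The classifier is linear by design; overlapping feature distributions
  (e.g. rim vs infiltrating chicken at similar local densities) bound its
  accuracy, and k-3 density does not transfer across nuclear densities
  without retraining.
- The IHC module scores OD over regions from this package's own
  segmentation; counts are not comparable to tools with their own cell
  detection.
- Fibre-morphology markers cover only part of a cell, so per-cell MFI for
  such markers is by construction lower than the rendered fibre intensity;
  positivity, not MFI, is the designed readout for them.
- Amplification efficiency is fixed at 2 unless overridden; no standard-curve
  calibration is implemented.
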