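# Methods

This note records the scientific and numerical choices behind `dynrad`:
what is computed, which decisions were genuinely open, and what the
synthetic studies do and do not demonstrate.

## Preprocessing

Each case holds four co-acquired 3D volumes (plain, arterial, portal
venous, equilibrium) with one binary tumor mask per phase. Volumes are
resampled to isotropic 1 mm (trilinear; masks nearest-neighbour so they
stay binary), then z-normalised, x′ = (x − μ)/σ. The normalisation
statistics are whole-volume by default — the transform is presented as an
image-level operation — with a `mask-only` switch. Resampling precedes
normalisation; the order is configurable in the pipeline and recorded in
the provenance sidecar. A constant region (σ = 0) is a degenerate input
and raises rather than silently producing zeros.

ROI intensities are quantised to gray levels 1–64 by equal-width binning
between the ROI minimum and maximum, so level 1 and level 64 are always
attained on a non-constant ROI and any monotone affine intensity
rescaling leaves the quantised ROI unchanged. A constant ROI maps to all
level 1 (convention, not an error). Fixed-bin-width quantisation is
deliberately not offered: the 1–64 convention is a fixed-bin-count
dialect.

No inter-phase registration is performed; per-phase masks are treated as
already co-registered. Bias-field and motion correction are out of scope.

## Static feature bank (484)

Per phase: 7 intensity + 53 texture + 8 × 53 wavelet-texture features.

- **Intensity (7):** mean, population variance, skewness and kurtosis as
  standardised central moments (kurtosis not excess-corrected; both 0 on
  a zero-variance ROI), energy Σx², entropy of a 64-bin equal-width
  histogram (log₂), and range. Computed on the normalised (unquantised)
  ROI values.
- **Texture (53):** 22 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM. The method's
  source names only the families and a handful of members; the concrete
  roster is this package's documented choice and ships as a versioned
  manifest (`FeatureRoster.to_json`). It includes every feature the
  motivating signatures name (Skewness, Variance, Maximum probability,
  Cluster prominence, Correlation1/2, Autocorrelation, Long run (low
  gray-level) emphasis, Gray-level variance, Small zone emphasis,
  Contrast). `Correlation1` is the Haralick form
  (Σij·p − μxμy)/(σxσy) and `Correlation2` the normalised-covariance form
  Σ(i−μx)(j−μy)p/(σxσy); they agree algebraically and serve as an
  internal consistency check.
- Matrices are built strictly inside the ROI: out-of-mask voxels never
  enter a pair, run, zone or neighbourhood. GLCM and GLRLM use the 13
  unique 3D directions at Chebyshev distance 1 and average the *feature
  values* over directions; GLCMs are symmetrised and normalised. GLSZM
  zones and NGTDM neighbourhoods use 26-connectivity. Degenerate ROIs
  follow fixed conventions instead of raising: a single-voxel ROI yields
  1×1 run/zone matrices and a self-pair GLCM; σ = 0 marginals give
  correlation 0; a flat NGTDM gives coarseness capped at 10⁶ and
  busyness/strength 0.
- **Wavelet (424):** one-level separable 3D transform, `coif1` by
  default (configurable). The stationary (undecimated) transform is used
  so all 8 sub-bands stay voxel-aligned with the mask; each sub-band ROI
  is re-quantised and run through the same 53-feature texture bank.
  Sub-bands are named by the filter applied along (x, y, z). A decimated
  periodic-boundary mode exists for energy-conservation checks with
  orthogonal wavelets.

## Dynamic features (20 per static feature)

Each static feature's 4-point trajectory is summarised by:
mean, population variance, coefficient of variation sd/mean (3);
RCR and RACR over the three consecutive segments (6); OLS line (k, d)
(2); LS parabola (a, b, c) plus curvature summaries (5); LS exponential
α·eᵗ + β — linear in (α, β) on the basis {eᵗ, 1} — plus curvature
summaries (4). 20 × 484 = 9680 per patient.

Decisions that were genuinely open:

- **RACR denominator.** The "relative average change rate" denominator is
  the mean of the feature over all four phases (default); a
  `segment-midpoint` mode (average of the two segment endpoints) is
  available. The series-mean reading matches the word "average" applying
  to the whole examination.
- **Segments.** Change rates are computed for the three consecutive
  segments (plain–arterial, arterial–portal, portal–equilibrium), with
  the earlier phase in the RCR denominator.
- **Exponential curvature.** The printed formula
  EK = |a·eᵗ| / (1 + a·e^{2t})^{3/2} with a := α is implemented verbatim
  as the default. It is *not* the exact curvature of α·eᵗ + β (that has
  α²e^{2t}, always positive); under the printed form the base can be
  non-positive for α < 0, in which case EK is NaN at those times and such
  points are excluded from the argmax (an all-NaN profile yields NaN
  summaries). `corrected_curvature=True` switches to the exact form.
- **Curvature summary times.** T_maxQK is the unconstrained parabola
  vertex −b/(2a); T_maxEK is a numeric argmax restricted to [t₁, t₄]
  (three-level grid refinement, final resolution < 10⁻⁶, since the
  printed EK has no interior-maximum guarantee). The "curvature at the
  maximum feature value" is evaluated at the time of the *observed*
  series maximum, earliest on ties.
- **Degeneracies.** a = 0: QK ≡ 0, T_maxQK := t₁. α snapped to 0 (and a
  likewise) when below 10⁻¹⁰ × max(1, |series|∞), so constant series hit
  the documented conventions instead of floating-point residue. Zero
  denominators (RCR at Ψ(tᵢ) = 0, CV at mean 0) give NaN, never an
  exception; NaNs are median-imputed inside the training split at
  modeling time.
- **Time grid.** Default t = (1,2,3,4) (phase indices): the fits are
  against an unspecified clock, and phase index is the only grid
  available for all four phases. Representative acquisition-delay seconds
  can be passed instead; the grid is recorded in the provenance sidecar.

The core is vectorised (`dynamic_block_matrix` processes
patients × features × 4 in one pass, chunked for the EK grid search);
the per-series functions are thin wrappers over the same code path.

## Signatures and evaluation

ICC filtering uses the two-way random-effects, absolute-agreement,
single-measurement ICC (ICC(2,1)) computed from the two-way ANOVA mean
squares, vectorised across features and cross-checked against an
independent implementation in the tests; a feature passes only if both
the intra-observer (reader 1 vs repeat) and inter-observer (reader 1 vs
reader 2) ICCs exceed 0.8. Zero between-subject variance leaves the ICC
undefined and the feature fails.

The SR/DR/DSR signatures share one pipeline, differing only in input
columns: training-median imputation → z-scoring → one-way ANOVA F-test
keeping p < 0.05 (α is a documented choice) → L1-logistic selection with
the inverse penalty C chosen on a log grid (10⁻² … 10^1.5, 8 points) by
repeated stratified 5-fold × 5-repeat CV maximising mean AUC, ties to the
stronger penalty, with a fall-back to the weakest penalty yielding a
non-empty selection → unpenalised logistic refit on the survivors →
Youden-optimal probability threshold on the training ROC. DSR re-screens
the union of the SR- and DR-selected columns. Every constant is
training-derived; the validation cohort is transformed with frozen
parameters and touched once, and a dedicated test verifies that permuting
validation labels changes no training artifact.

AUC uses the Mann–Whitney rank formulation; its CI and the paired
signature comparison use the DeLong covariance of the ROC-area
U-statistic (implemented in-package; normal-approximation two-sided test;
degenerate variance reports p = 1). The comparison test itself is a
documented choice — the procedure being reproduced names none.

## Synthetic data: what it shows and what it does not

The voxel phantoms emulate the *statistical structure* the pipeline
assumes: 4 phases, an ellipsoidal lesion whose mean intensity follows a
class-specific trajectory (default: MVI-negative 100→160→150→130,
MVI-positive 100→185→140→112 — stronger wash-in, faster washout), a
spatially correlated texture field whose correlation length and amplitude
differ by class, additive Gaussian noise (σ = 5, Rician optional), and
masks equal to the lesion support, optionally jittered through a signed
distance + smooth random field re-threshold to simulate readers. They do
not emulate liver anatomy, MR physics, partial-volume effects or
registration error, so passing tests demonstrate pipeline correctness —
not clinical performance.

The feature-series generator works at the level the models see.
Its `temporal-only` design draws each informative feature as
baseline + s·A·profile + noise with a random sign s = ±1 per
patient-feature, where class 0 uses a monotone profile (−1.5,−0.5,0.5,1.5)
and class 1 a zigzag permutation of the *same per-phase amplitudes*
(−1.5,0.5,−0.5,1.5). Both classes therefore have exactly the same
per-phase marginal distributions — any linear static classifier has
population AUC ½ — while the absolute segment changes differ
((2,1,1)·A vs (4,1,2)·A), which the discrete dynamic features capture.
Defaults: baseline 10, amplitude A = 1, noise sd 0.6, 15% informative
features, prevalence 0.4. The `none` design is an exchangeable null used
for calibration; `marginal` plants an arterial-phase mean shift visible
to static models.

## Study sizes and numerical tolerances

The shipped studies use phantom volumes of 20–28³ voxels with 4–8 mm
lesions, feature-series cohorts of 200–300 training / 150–400 validation
patients and 200 features, and ten seeds for the temporal-recovery
summary; these sizes give stable medians while keeping a full run in
minutes. Null calibration evaluates the fixed models on a 400-patient
validation draw because the chance-level AUC of a fixed model has
sd ≈ 1/√n_val and smaller draws measure noise rather than bias.
Noiseless fit recovery is asserted at 10⁻⁸, texture-matrix oracle
agreement at 10⁻¹⁰, probability normalisation at 10⁻¹², and the wavelet
Parseval check (decimated, orthogonal) at 10⁻⁶ relative.

## Known limitations

- The 53-feature texture roster is a reconstruction; other banks
  (e.g. different GLCM subsets or additional GLDM features) would change
  individual feature values while preserving the 7/53/424 accounting.
- The printed exponential curvature produces NaN summaries for decaying
  trajectories (α < 0) over much of the time window; downstream
  imputation absorbs this, but users wanting a geometrically meaningful
  curvature should enable `corrected_curvature`.
- Phase index as the default time grid makes the fitted parameters
  unitless; switching to acquisition seconds rescales k, a, b and the
  exponential basis nonlinearly.
- Stationary wavelet sub-bands are redundant (not energy-preserving);
  energy-based comparisons across sub-bands are only meaningful in the
  decimated mode.
- With strong separable signal, L1 selection on null columns can still
  admit noise features (the CV-AUC surface is flat under the null);
  the signatures' validation AUC, not the selection count, is the
  calibrated quantity.
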