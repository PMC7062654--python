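# Methods

`dwiradiomics` implements a classical two-dimensional texture-radiomics
pipeline for apparent-diffusion-coefficient (ADC) maps of breast lesions, in
the style popularized by the MaZda texture-analysis program, together with a
synthetic DWI/ADC cohort simulator used to validate every stage. This note
records the models, the conventions that had to be fixed where the method
family leaves them open, and what the synthetic experiments do and do not
demonstrate.

## ROI normalization

All histogram, co-occurrence, run-length and autoregressive features operate
on quantized gray levels. For each ROI the dynamics are limited to
μ ± 3σ, where μ and σ are the mean and *population* standard deviation
(divisor N) of the masked pixels — the limit is a per-ROI dynamics clamp,
not an inferential estimate, so the population form is used. Clipped values
map linearly to integer levels 1..Ng via

    level = 1 + floor((x_clip − (μ−3σ)) / (6σ) · Ng),

with half-open bins and the top edge closed, so exactly Ng levels are
reachable and x = μ+3σ maps to Ng. A bitwise-constant ROI (σ = 0) maps
entirely to level 1, keeping downstream matrices well defined instead of
erroring. Ng defaults to 64 (6 bits) for every family and is configurable
per family (`his_levels`, `glcm_levels`, `rlm_levels`); the clip width of 3σ
is fixed. Quantization makes these families invariant under positive affine
intensity rescaling, which stands in for scanner gain/offset variation.

## Feature families

The catalogue is frozen per configuration (276 names at the defaults) and
every lesion yields a value or an explicit missing (NaN) for each name.

* **HIS** — mean, population variance, skewness, excess kurtosis and the
  1/10/50/90/99 percentiles (linear interpolation) of the level
  distribution. Skewness/kurtosis of a zero-variance ROI are missing.
* **COM** — symmetric, normalized gray-level co-occurrence matrices for
  distances 1..5 and directions 0°/45°/90°/135° (ordered pairs counted in
  both opposite offsets). Eleven Haralick-type descriptors per matrix:
  angular second moment, contrast, correlation, sum of squares, inverse
  difference moment, sum average, sum variance, sum entropy, entropy,
  difference variance, difference entropy. All entropies use the natural
  logarithm with 0·log 0 := 0; the base only rescales the features and the
  selection/classification stages are scale-tolerant, but it is fixed here
  for reproducibility. Sum variance is taken about the sum average (not the
  sum entropy); difference variance is the variance of the |i−j|
  distribution. Correlation is missing when a marginal has zero variance;
  a (distance, direction) with no valid in-mask pair yields missing values.
* **RLM** — run-length matrices in the same four directions; runs are
  maximal same-level sequences along in-mask collinear segments, broken by
  mask boundaries. Descriptors: short- and long-run emphasis, gray-level
  and run-length nonuniformity, and the fraction of image in runs
  (total runs / ROI pixels).
* **Absolute gradient** — magnitude of the central difference,
  √(Δv² + Δh²)/2, on *raw* intensities, over pixels whose 4-neighbourhood
  lies inside the mask; mean, variance, skewness, excess kurtosis and the
  fraction of nonzero gradients.
* **ARM** — a causal autoregressive model on mean-centered levels,
  x(i,j) = θ₁x(i,j−1) + θ₂x(i−1,j) + θ₃x(i−1,j−1) + θ₄x(i−1,j+1) + e,
  fitted by least squares over pixels whose four causal neighbours are in
  the mask (minimum 20, else missing); rank-deficient systems take the
  minimum-norm solution. Reported: θ₁..θ₄ and the residual SD.
* **WAV** — a non-standard (separable, orthonormal) Haar decomposition of
  the mask's bounding box on raw intensities with the ROI mean removed
  (outside-mask pixels therefore contribute zero). At each scale the LL,
  LH, HL and HH subband energies are the mean squared coefficients over
  coefficients whose full 2^s × 2^s spatial support lies inside the mask
  (the fully-supported-coefficient rule, chosen over inscribed-square
  cropping so irregular freehand-style ROIs are used maximally). Naming:
  the first letter filters the row axis, so HL is the vertical-difference
  subband. Trailing odd rows/columns are dropped at each level. On a full
  dyadic box the decomposition is exactly orthonormal (Parseval holds to
  1e-9 and the subbands match PyWavelets' `wavedec2`).
* **Geometry** — area (pixel count × pixel area), perimeter, circularity
  4π·area/perimeter², elongation (minor/major axis ratio from second-order
  central moments of pixel centers) and maximal Feret diameter (largest
  pixel-center distance), all in physical mm units. The perimeter is
  algorithm-defined: the length of the Moore-traced 8-connected boundary
  path through pixel centers (axial steps count one pixel spacing, diagonal
  steps the corresponding hypotenuse). Pixel-center perimeters carry a
  sub-pixel negative bias, so circularity can slightly exceed 1 for
  near-circular rasterizations; comparisons against an equal-area disk are
  made with a small rasterization slack.

Raw-intensity families (gradient, WAV) deliberately bypass quantization;
HIS/COM/RLM/ARM operate on levels — mirroring the customary split in this
method family.

Feature maps recompute any single catalogue feature in a sliding window
clipped to the mask, for visualization of spatial heterogeneity; the map
value at a pixel equals the feature computed on that clipped window ROI.

## Feature selection

Three criteria rank candidate features of a binary task; candidates must be
complete and non-constant (exclusions are recorded with reasons), and all
ties break by catalogue order, making selection deterministic. Each returns
the top ten by default.

* **Fisher** — between-class over within-class variance (population forms,
  class-size weighted). Perfect separation yields +∞, ranked first.
* **POE + ACC** — greedy Mucciardi–Gose selection: the first feature
  minimizes the probability of error (POE) of the best single-threshold
  classifier (exhaustive scan over thresholds midway between consecutive
  distinct values, both polarities — deterministic and parameter-free);
  feature j+1 minimizes POE(f) + (1/j)·Σ|Pearson r(f, s)| over the already
  selected s, on raw values with 1:1 weighting.
* **MI** — mutual information (nats) between the class label and the
  feature discretized into 8 equal-frequency bins (duplicate quantile edges
  merged); invariant under strictly monotone transforms.

A known behaviour of POE + ACC worth recording: when several informative
features owe their discrimination to the *same* class contrast, that
contrast itself induces pooled-sample correlation between them (for a shift
of Δ pooled SD, r ≈ (Δ²/4)/(1+Δ²/4), i.e. 0.5 at Δ = 2). The redundancy
penalty then exceeds the POE advantage of further informative features and
the greedy picks uncorrelated noise instead. On the planted-feature
benchmark (10 informative of 50, Δ = 2, n = 25/class) Fisher and MI recover
≈10/10 and ≈9.9/10 informative features on average while POE + ACC recovers
≈5/10 — not an implementation defect but a property of the 1:1
POE-plus-average-correlation cost, which was kept in its standard form.

## Classification

Each selected set is z-scored (training statistics), reduced to a single
most-discriminatory-feature (MDF) coordinate by the Fisher discriminant
w = S_w⁻¹(m₁ − m₀) with pooled within-class scatter, and classified by
k-nearest neighbours (default k = 1, odd k configurable) under
leave-one-out cross-validation with the misclassification percentage as
outcome. A singular scatter (e.g. duplicated features, or 10 features with
8 lesions in a class) receives diagonal shrinkage S_w + λ·tr(S_w)/p·I with
λ = 1e-3, then a pseudo-inverse if needed; the report flags when shrinkage
fired. Sign convention: the task's second class has the higher projected
mean. Distance ties break toward the lower lesion index, even vote splits
toward the larger class and then the lower label order, so a fixed table
and configuration give a bit-identical report.

Two evaluation protocols are provided and labelled rather than silently
choosing one:

* **FULL** — selection and LDA fitted once on the full task data; LOOCV
  wraps only the k-NN vote. This is the literal historical protocol. It is
  *optimistic*: on null cohorts (identical class generators, n = 25/class,
  ~130 candidate features) its best-of-three accuracy averages ≈70 %,
  because the held-out lesion influenced both the feature choice and the
  projection.
* **NESTED** — selection and LDA refitted inside every fold. On the same
  null cohorts its best-of-three accuracy averages ≈53–54 %; the residual
  3–4 points above chance are the maximum over three correlated criteria
  (a multiplicity effect), not information leakage.

The task enumerator runs every unordered class pair, every class against
the rest, and any label-derived contrasts declared in the manifest (e.g.
hormone-receptor-positive = luminal A + luminal B), producing a symmetric
accuracy grid with the best criterion per cell and an ≥80 % clinical-
relevance flag. Cells whose groups have fewer than two lesions are marked
not computable.

## Synthetic cohorts

The simulator emulates the measurement chain, not breast anatomy. Each
lesion is a star-convex blob (radius R·(1 + low-order sinusoids), clipped
to ±30 % of R, radii 7–11 px by default on a 48×48 grid at 1.4 mm pixels)
whose latent ADC field is mean + SD·GRF(ℓ): a Gaussian random field built
by convolving white noise with a Gaussian kernel and renormalizing to unit
variance. The correlation length ℓ is the lag at which the autocorrelation
falls to e^(−1/2) (kernel σ = ℓ/√2); it is the main texture dial because it
maps directly onto GLCM/RLM contrast between classes. Background tissue is
fluid-like (ADC 2.4×10⁻³ mm²/s) with its own texture; a peritumoral rim of
width 2 px (Chebyshev metric, configurable) takes intermediate values, so a
mask dilated by the rim width imports off-lesion statistics — the analogue
of delineating on high-b DWI and propagating the ROI, versus the exact blob
mask as delineation on the ADC map itself. Signals are b₀ = S₀ + noise and
S_b = S₀·exp(−b·ADC) + noise with b = 1000 s/mm², S₀ = 600 and Gaussian
noise at SNR 50; the reported ADC map is recomputed as ln(b₀/S_b)/b from
the noisy pair (signals floored at 10⁻⁴·S₀ before the log, clips counted),
so acquisition noise propagates into the analysis substrate exactly as it
would on a scanner.

The four default class specs stand in for the molecular subtypes with
plausible malignant-breast ADC means (0.95–1.28×10⁻³ mm²/s) and distinct
correlation lengths (1.2–3.6 px); the default cohort mix is 49/8/11/23
lesions so the small-class regime (8 lesions against 10 features) is
exercised. These parameters are invented stand-ins — no per-subtype texture
ground truth exists — so subtype-labelled results on synthetic data
demonstrate pipeline behaviour under a *known* contrast, never clinical
performance. What the simulator does not model: 3-D structure, coil/bias
fields, EPI distortion, perfusion (IVIM) effects, T2 shine-through, and
observer variability in freehand delineation.

## Validation experiments and problem sizes

The replicate experiments in the acceptance suite and `scripts/acceptance.py`
use 48×48 images, n = 25 lesions per class, SNR 50, rim width 2, and a
scaled texture configuration (GLCM distances {1, 2}, Haar scales ≤ 2,
~130 features) — the package's chosen problem sizes for replicate studies;
the single default-cohort run uses the full 276-feature configuration.

* Brute-force oracle equivalence of all seven families on random ≤8×8 ROIs
  (tolerance 1e-9), plus exact closed-form fixtures.
* Planted-feature selection recovery (see above).
* Null calibration over replicate cohorts with identical generators:
  FULL-mode mean ≥ NESTED-mode mean (selection optimism), NESTED centered
  near chance.
* Effect recovery: a 3:1 correlation-length contrast (ℓ 1.2 vs 3.6) is
  detected at ≥90 % LOOCV accuracy in ≥80 % of replicates.
* Segmentation-variant ordering: on rim-contaminated cohorts with a
  moderate contrast (ℓ 1.4 vs 1.8, chosen so neither variant saturates at
  100 %), exact masks average ≈94 % versus ≈81 % for dilated masks —
  the qualitative analogue of tumor delineation directly on the ADC map
  outperforming propagated high-b ROIs. Only the ordering, never specific
  percentages, is asserted.
* End-to-end determinism: identical (cohort seed, configuration) produce
  byte-identical CSV/JSON artifacts.

## Numerical choices and degenerate inputs

Minimum ROI size is 16 pixels (the smallest region on which a 2-level GLCM
and one Haar scale are defined; at 1.4 mm pixels the conventional ≥1 cm
lesion criterion comfortably exceeds it); masks must be a single
8-connected component. Default pixel spacing is 1.4 mm isotropic when a
format carries none (NIfTI headers win when present; note NIfTI stores
pixdim as float32, so mm-unit geometry features round-trip only to ~1e-7
relative). Feature tables serialize floats at 17 significant digits and
missing values as empty cells. All randomness flows from
`numpy.random.Generator` seeds recorded in the outputs.

## Known limitations

Single-slice 2-D analysis only; no DICOM series handling; the feature
catalogue is a reconstruction of the customary MaZda families rather than
an IBSI-certified set (conventions are documented above instead); the
FULL protocol is reported because it is the historical one, but its null
optimism (~70 % vs ~53 % nested) means NESTED mode is the honest choice for
any new claim; and synthetic-cohort accuracies characterize the pipeline,
not breast cancer.
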