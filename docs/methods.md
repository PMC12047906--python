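# Methods

This note documents the models, numerical choices and known limitations
behind `cervimetry`. It is written for maintainers and for users who need
to judge what the synthetic validation does and does not demonstrate.

## Coordinate conventions

All volumes are reoriented on read to the closest right-handed RAS frame
(+x left→right, +y posterior→anterior, +z inferior→superior). Voxel
indices are 0-based and refer to voxel centres; the world position of
index `i` is `origin + axes · (i ∘ spacing)` in millimetres. The sagittal
plane — the measurement plane of the clinical protocol — is taken as the
plane orthogonal to the x axis of this frame; source data do not state an
orientation convention, so normalising on read is what makes biometry
orientation-stable. Landmark and measurement outputs are world-mm,
reported at 0.01 mm resolution with an accuracy contract of roughly one
voxel: sub-voxel digits are reproducible, not anatomically meaningful.

## Phantom model

The phantom is a parametric idealisation of the pregnant cervix designed
so that the measurement protocol's own geometry is exactly recoverable:

* **Centreline** — two straight segments of equal length joining the
  internal os (inlet), the canal midpoint, and the external os (outlet),
  bent by `bend_angle` in the sagittal plane. This mirrors the two-line
  cervical-length protocol, making `true_cervical_length = canal_length`
  by construction. A curved (spline) centreline is deliberately not the
  default: with a piecewise-linear truth the measurement error decomposes
  cleanly into rasterisation effects and the algorithm's own bias.
* **Layers** — coaxial tubes: canal radius linearly interpolated from
  `inlet_diameter/2` to `outlet_diameter/2` (power-law exponent
  `canal_taper`), wrapped by `inner_thickness` of inner stroma and
  `outer_thickness` of outer stroma. The two segments meet in a mitred
  (bisector-plane) joint, so the elbow tiles without gap or overlap and
  the closed-form shell volumes are exact for a taper-free tube at any
  bend angle (the oblique cut through the axis exchanges congruent
  wedges); with taper the residual is second-order. Tubes are open at
  both ends: the canal touches background exactly at the two os discs,
  which is what the interface-based landmark extraction requires.
* **Cysts** — hyperintense spheres placed inside the canal lumen with
  arc-position drawn from a Beta(1.5, 6) distribution toward the inlet
  with probability `cyst_inlet_bias` (cysts are predominantly an inlet
  finding); radii are clipped so the sphere stays inside the canal. Truth
  volumes use the sphere formula; overlapping cysts are merged in the
  raster, so with multiple large cysts the analytic cyst volume is an
  upper bound — cohort defaults keep cysts small and sparse.
* **Bladder** — a hyperintense ellipsoid (semi-axes 12×9×14 mm) anterior
  to the inlet. It matters for two reasons: it is a trained label, and it
  anchors the inlet/outlet disambiguation rule.
* **Contrast** — two per-label mean-intensity presets (`high_field`,
  `low_field`) whose ordering follows the protocol descriptions: cysts
  and bladder hyperintense, canal mixed but brighter than stroma, inner
  stroma dark, outer stroma intermediate and slightly darker than the
  surrounding soft tissue (rendered as the background value). Absolute
  values are arbitrary units; the low-field preset compresses contrast
  and makes cysts markedly less conspicuous. Canal mottling (smooth
  Gaussian field, ≈2 mm correlation length) emulates heterogeneous mucus
  signal; a multiplicative random quadratic bias field (±20% default) and
  Gaussian noise (5% of the contrast range) complete the image model.

**What the phantom does not emulate:** motion-correction residuals,
partial-volume blur at interfaces, anatomy-dependent stromal texture,
funneling/short-cervix/scar pathology, and the poorly visible outer
boundary of real outer stroma. Passing the synthetic tests therefore
demonstrates correctness of the geometry, training machinery and
statistics — not clinical-grade segmentation accuracy.

### Cohort simulation

`generate_cohort` draws per-subject geometry around gestational-age
trends chosen to match the direction of the reported physiology:
cervical length 40 mm at 16 weeks falling 0.3 mm/week (between-subject
SD 2.5 mm), inlet diameter 6 mm rising 0.1 mm/week (SD 0.7 mm), outlet
diameter drifting −0.02 mm/week (SD 0.6 mm); bend angle N(20°, 10°) in
[0°, 45°]; cysts present in 36% of cases; field strength 0.55 T with
probability 0.47 (switching only the contrast preset, never geometry);
maternal age/height/BMI from plausible obstetric ranges. The configured
effects are recorded so chart fitting is validated by parameter
recovery, not by comparison to clinical values.

## Biometry algorithm

Interface voxels are canal-or-cyst voxels with a face-adjacent (6-
connected) background neighbour, grouped by 26-connectivity; the two
largest components are the os ROIs (more than two sets a quality flag,
fewer than two is an error — e.g. a capped canal). The inlet is the
component nearer the bladder centroid when a bladder label exists,
otherwise the more superior-anterior one. Centrepoints and the canal
midpoint are unweighted means of voxel-centre world coordinates; the
length is the exact two-segment sum. Diameters march from the (slightly
inward-nudged) centrepoint along the in-sagittal-plane direction
perpendicular to the adjoining centreline segment, at quarter-voxel
steps, ending at the first inner-stroma voxel per side; the chord is
bounded by the inner surface of the inner layer (the alternative outer-
surface convention is a `boundary_codes` switch). Running into
background or off the volume flags the result instead of failing it.

Two systematic effects bound the accuracy against parametric truth:
(1) interface-voxel centres sit up to half a voxel inside the true end
plane (≈0.5–0.8 mm shortening over both ends at 0.8 mm voxels); (2) for
a bent canal the mean canal coordinate is not the centreline vertex, so
the two-line length through it is shorter than the arc length by
`L(1 − √(1 − 0.75 sin²(bend/2)))` — about 0.9 mm at 30° and 1.9 mm at
45° for a 35 mm canal. Both are properties of the specified protocol,
not implementation error; the measured-vs-truth tolerance used in the
validation (mean ≤2 voxels over the phantom grid) budgets for them.

## Segmentation network

A standard 3D encoder-decoder: per level, `convs_per_block` units of
(3³ convolution → batch normalisation → ReLU); 2× max pooling between
encoder levels; the decoder upsamples by nearest-neighbour ×2 followed by
a 3³ convolution, concatenates the skip connection and convolves again;
dropout after the bottleneck; a 1³ convolution produces 6-class logits.
Resize-convolution was chosen over transposed convolution for the
decoder: equal expressiveness at kernel 3, a simpler exact adjoint, and
no checkerboard artefacts. Batch normalisation at batch size 1 uses
per-channel spatial statistics with running estimates for inference.

The loss is soft Dice (mean over classes, ε = 10⁻⁵) plus voxel-mean
cross-entropy, equally weighted (both weights are config fields). AdamW
(β = 0.9/0.999, weight decay 10⁻⁵, decoupled) with a learning rate
decaying linearly from `lr_init` to `lr_floor` (default 0) across the
run. Augmentation is applied on the fly with per-iteration seeds derived
from the global seed: rotation (trilinear image / nearest labels, angles
uniform within ±45° per axis), multiplicative quadratic bias field, and
gamma contrast adjustment; intensity transforms never touch the labels.
Images are z-scored per volume; when a training set mixes contrasts,
piecewise-linear quantile-landmark histogram matching to the first
case's profile is applied (the conventional landmark method), and the
reference landmarks are stored with the model.

The engine is pure numpy with fused direct-convolution kernels compiled
by numba (an im2col/GEMM fallback keeps the package functional without
numba, several-fold slower). Forward/backward passes are covered by
finite-difference gradient tests, and the two convolution paths are
cross-checked against each other.

### Full-scale vs desk-scale recipes

`NetConfig()` defaults to the full-scale recipe: 128³ grid, channels
(32, 64, 128, 256, 512), two convolutions per block, dropout 0.5,
lr 10⁻³, 100 000 iterations. That configuration is impractical to
validate routinely on CPU, so `NetConfig.reduced()` defines the
desk-scale recipe used by the test-suite and the acceptance script:
64³ grid, channels (8, 16, 32, 64, 128), one convolution per block,
dropout 0.1, 300 iterations, lr decaying 3×10⁻³ → 6×10⁻⁴ (a
few-hundred-iteration run needs a hotter start than a 100k-iteration
schedule, and a non-zero floor keeps the late iterations learning the
hard canal class), reduced augmentation probabilities (rotation 0.15,
bias/contrast 0.25). Cohorts are resampled to the smallest common
isotropic spacing (0.1 mm steps, floor 0.8 mm) that fits every case's
*cervix* — canal, stromal layers, cysts — into the grid with a 4-voxel
margin; the bladder may be truncated at the FOV edge, exactly as in a
cropped reconstruction. Keeping the cervix at native 0.8 mm matters:
at a bladder-inclusive ≈1.3 mm the canal is only ~2 voxels of radius
and held-out canal Dice drops from ~0.9 to ~0.6. At these sizes a
25-phantom train/evaluate cycle takes on the order of ten minutes on a
single CPU and reaches held-out mean foreground Dice above 0.8 with
pooled per-label volume ICC above 0.9. The known failure mode is small
cysts (1–2 voxel spheres), which the 300-iteration recipe does not
detect — a case-level Dice penalty on the ~36% of cases carrying
cysts — while the mottled canal is the weakest of the learned classes,
mirroring where the full-scale problem is hard.

Semi-supervised staging is exposed as `pseudo_label_round`: predict on
unlabelled images, optionally pass each prediction through a refinement
callback (standing in for manual editing), retrain on the union.

## Charts and statistics

Trends are least-squares polynomials in GA (degree 1 default, degree 2
optional, AIC selection via `degree="auto"`), with homoscedastic
Gaussian centiles: 5th/95th = mean ∓/+ 1.645·residual-SD, 50th = mean.
Under this model centiles cannot cross and the median equals the mean
curve. ANCOVA is a single linear model `response ~ GA + covariates`
with type-II sums of squares (order-invariant adjustment); categorical
covariates (field strength, ethnicity) enter as factors; rank-deficient
designs raise rather than silently alias. Field strength is fitted in
the same model as the maternal covariates by default; restricting the
covariate list reproduces a separate-analysis variant. Agreement uses
ICC(2,1) — two-way random effects, absolute agreement, single measure —
computed from the ANOVA mean squares; it penalises systematic bias
(unlike Pearson correlation), generalises to k raters, and returns a
flagged null when total variance is zero. The implementation is
cross-checked in the tests against an independent implementation
(pingouin) and a hand-computed mean-squares table.

Validation is by parameter recovery on synthetic cohorts: the configured
−0.3 mm/week length slope is recovered within its 95% CI at n = 100, a
configured +200 mm³ field-strength offset is recovered by the ANCOVA,
the GA term holds its nominal type-I error (~5%) across 200 null
replicates, and the 5th–95th centile band covers ≈90% of fresh samples.
The original chart magnitudes and p-values from clinical cohorts are
explicitly not reproduction targets.

## Degenerate inputs and tie-breaks

Empty canal, capped canal (no canal-background interface), and single-
interface segmentations are errors with diagnostic messages; more than
two interface components keeps the two largest and flags. A constant
response yields a zero-slope trend with a warning. Zero-variance ICC
input returns a flagged null. Max-pooling gradient ties are split evenly
(mass-conserving). Quantile landmarks are made non-decreasing before
histogram matching. Bends whose plane deviates more than 10° from
sagittal are flagged, not rejected.

## Known limitations

* The phantom geometry is idealised (circular cross-sections, sharp
  interfaces); real cervices have elliptic, irregular lumens.
* Analytic cyst volumes ignore cyst-cyst overlap (merged in the raster).
* The desk-scale network is not the full-scale recipe; its scores bound
  the machinery, not clinical performance, and no trained weights are
  shipped.
* Angular, cross-sectional-area and stroma-area biometry, funneling
  detection and abnormal-anatomy handling are out of scope.
* DICOM ingestion and slice-stack (2D multi-slice) data are out of
  scope; inputs are 3D isotropic reconstructions in NIfTI.
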