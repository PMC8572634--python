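# Methods

## Problem setting

`cowseg` reproduces, on fully synthetic data, an analysis workflow for
head-neck CTA: segment the cerebral/cervical arteries with a multitask
convolutional network, decide per Circle-of-Willis (CoW) segment whether it
is *normal* or a *variation* (absent or severely hypoplastic), grade focal
stenoses on the NASCET scale, and compare variant prevalences between
matched patient groups with chi-square tests on 2×2 tables. Clinical CTA
and expert annotations are replaced by a phantom generator whose ground
truth is exact, so every downstream rule can be tested mechanically.

## Phantom generator

A phantom is a 3D HU-scale volume plus a binary vessel mask on the same
grid. The arterial tree contains 18 segments: the afferent vessels (ICA ×2,
VA ×2, BA), the communicating ring (A1 ×2, Aco, P1 ×2, Pco ×2), the middle
cerebral stems (M1 ×2), and post-communicating stubs (pACA ×2, pPCA ×2).
Centerlines are natural cubic splines through hand-designed waypoints
expressed as fractions of the volume's physical extent; the layout encodes
*topology* (what connects to what, which segment is thinnest), not
patient-specific anatomy, because the segmentation and classification rules
under test depend only on topology and caliber.

Default radii (mm): ICA 2.0, BA 1.8, VA 1.4, M1 1.5, A1/P1 1.1, pACA/pPCA
1.0, Pco 0.8, Aco 0.6. The Aco is deliberately the thinnest ring segment —
sub-voxel-caliber communicating arteries are the recognized hard case for
both visual and automatic detection — so the "difficulty ordering"
experiments have a built-in easy-to-hard axis (P1 ≥ Pco ≥ Aco).

Ground-truth manipulations:

* **Status.** `absent` segments are simply not rasterized. `hypoplastic`
  segments have their radius scaled to 25 % of the contralateral homologue,
  safely past the "more than 70 % thinner" variation threshold so the
  classification ground truth is unambiguous. Hypoplasia is only drawn for
  a segment whose homologue is normal (otherwise absence is drawn), again
  to keep ground truth unambiguous.
* **Stenosis.** A cosine-shaped radius dip centred at a fractional position
  along the centerline, spanning ~12 % of the segment length, reaching
  `1 - severity/100` of the nominal radius at its centre. Severity is
  strictly < 100 (a 100 % "stenosis" is an occlusion, which the measurement
  op reports but the generator does not produce).

Rasterization: the binary mask contains exactly the voxels whose *centre*
lies within the local radius of some non-absent centerline (verified in the
tests against a brute-force all-voxels × all-samples distance oracle). The
intensity volume blends tissue and vessel HU by sub-voxel occupancy
estimated on a 3×3×3 sub-grid per boundary voxel, so thin vessels show
realistic partial-volume dimming. The head is a soft-tissue ellipsoid with
a thin bone shell and air outside; a low-order random polynomial bias field
(default ±10 %) multiplies the contrast and Gaussian noise (default SD
15 HU) is added. Default intensities: air −1000, tissue 40, vessels 350,
bone 1200 HU. Everything is drawn from one seeded generator: identical
specs with identical seeds are bit-identical.

Cohorts draw per-segment variation indicators independently. The default
frequencies reproduce the young-normal per-patient prevalences of the
study population (Aco 36 %, A1 11 %, Pco 85 %, P1 25 %); for bilateral
segments the per-side probability p solves 1 − (1−p)² = per-patient rate.

What the generator does *not* emulate: vessel tortuosity and tapering,
kissing-vessel ambiguity, realistic skull base anatomy, contrast timing
artifacts, scanner noise spectra. Passing tests therefore show that the
method behaves correctly *given its own assumptions* (tubular bright
vessels in noisy inhomogeneous surroundings); they do not certify clinical
performance.

## Preprocessing

Volumes are resampled to isotropic 0.5 mm (trilinear for intensities,
nearest-neighbour for masks; output shape `round(shape·spacing/target)`),
clamped to the [0, 2000] HU band and rescaled to [0, 1] (clamping rather
than voxel deletion keeps the grid intact for the reconstruction task),
then cut into per-slice axial patches, centre-cropped or zero-padded to a
fixed side. Augmentation is restricted to the 8-element dihedral group
(90° rotations and flips): arbitrary-angle rotation would require
interpolating binary masks. Whether vessel-free slices are dropped is a
config flag, default off.

## Network and loss

The model is a 2D slice-wise encoder-decoder: `levels` (default 4) conv
blocks (3×3 conv → batch norm → ReLU) with 2×2 max-pooling between levels;
an ASPP bottleneck concatenating parallel dilated 3×3 convolutions (rates
1, 2, 4, 8) with a global-average-pooling image branch, fused by a 1×1
block; a decoder with factor-2 bilinear upsampling and skip concatenation;
and 1×1 heads. The multitask variant outputs the segmentation probability
map `O` (sigmoid) and two reconstruction images `F` (foreground) and `B`
(background), both linear in windowed-intensity units; the single-task
baseline keeps only `O` and is otherwise identical.

Vessels are a sparse foreground, so the segmentation head's bias is
initialized to the logit of a small prior (−3, i.e. initial probability
≈ 0.05) rather than 0; starting at 0.5 everywhere puts the per-image soft
Dice on a plateau and was observed to stall training for several epochs.
This is the standard rare-class prior initialization for dense prediction.

The loss is

    J = mean[(I − (F·O + B·(1−O)))²]  +  mean_batch[1 − 2Σ(O·S) / (ΣO² + ΣS² + ε)]

with per-image spatial sums in the Dice term and ε = 1e-6 (so two entirely
empty maps count as perfect agreement). The reconstruction term supervises
`O` as the blending weight that best explains the input as a
foreground/background mixture — unlabeled structure in the image therefore
shapes the segmentation features, which is the mechanism behind the
multitask advantage. The two terms are weighted 1:1 by default
(configurable).

The whole network is implemented in numpy with hand-derived analytic
gradients (im2col convolutions, batch-norm backprop, exact transposes for
pooling and bilinear upsampling). This keeps the package free of a deep
learning runtime and makes the gradients auditable: the test suite checks
every layer against central finite differences in float64 and the loss
against a per-pixel brute-force oracle. Unstated architectural details were
fixed as: ReLU nonlinearity, batch normalization per conv block, He
initialization, bilinear (not transposed-conv) upsampling, sigmoid on `O`
and linear `F`/`B` heads, binarization threshold 0.5 — all standard for this
architecture family and all configurable where they plausibly matter.

Training uses Adam. `TrainConfig` defaults follow the reference protocol
(learning rate 1e-4, 50 epochs, batch 32, slice side 288); these suit long
training on clinical-scale data.

## Desk-scale experiment profile

The bundled experiments (`cowseg.experiments`) run in minutes on one CPU
and measure *relative* claims only:

* cohorts of 6 training / 4 validation / 12 test phantoms at 64³ voxels,
  0.5 mm spacing, generated at harder-than-default imaging conditions
  (noise SD 40 HU, bias amplitude 0.2, vessel enhancement 300 HU): at the
  default difficulty both arms saturate near Dice 0.95 and the comparison
  would only measure noise, whereas the multitask mechanism —
  reconstruction as a regularizer when labels are scarce — needs task
  headroom to be observable;
* `base_filters` 8 (~105 k parameters), 64² patches;
* 4 epochs over left-right-flip-augmented patches, batch 8, Adam 1e-3.
  The step size is scaled up with the shortened schedule: at 1e-4 the Dice
  term barely moves within 10 epochs at this problem size, which would
  make any between-model comparison meaningless. Flip augmentation (a
  subset of the full training protocol's rotation-and-flip augmentation)
  prevents the model from learning side-specific vessel priors on such a
  small cohort — without it the model was observed to hallucinate a
  left posterior communicating artery where the training cohort happened
  to have one more often. Both arms of every comparison share the cohort,
  seed and schedule, so profile choices cancel out of the comparisons.

Absolute Dice on phantoms is not meaningful (at default difficulty the
models reach ~0.95; vessels in clinical data are far harder); the
experiments assert orderings:
multitask ≥ single-task mean held-out Dice over 3 paired seeds, and
detection accuracy P1 ≥ Pco ≥ Aco. The detection test cohort draws its
variations as absences only: a hypoplastic segment (25 % caliber, well
under one voxel) rasterizes to a handful of scattered voxels yet would
count as "present" ground truth, which would measure a labeling artifact
rather than caliber-dependent difficulty.

## Evaluation rules

**Dice.** Exact set overlap 2|O∩T|/(|O|+|T|) on binary masks; both-empty
scores 1 by convention. (In the evaluation context `T` is the ground-truth
mask; the symbol `F` is reserved for the reconstructed foreground.)

**Segment detection.** Expert visual review of "was this segment captured"
is replaced by a mechanical surrogate: a segment is called present when at
least 50 % of its ground-truth centerline samples fall inside the
prediction dilated by one voxel. Samples within 1.5 mm of either centerline
end are excluded: the endpoints lie inside the neighbouring arteries'
lumina, so without the trim a correctly segmented neighbourhood would
"cover" the stumps of an absent communicating segment — the same ambiguity
that makes close bilateral ACAs read as an Aco on real angiograms. The rule
is deterministic and documented precisely so that its numbers are
reproducible; it is *not* a validated stand-in for expert judgement.

**Stenosis measurement.** NASCET percent stenosis needs a minimal and a
reference lumen diameter. Local diameters are taken as twice the inscribed
sphere radius — the Euclidean distance transform of the mask interpolated
along the centerline — which for a circular lumen equals the perpendicular
cross-section diameter but is robust to centerline curvature and oblique
cuts near junctions (plane-sampled areas were measured to be biased by up
to 16 percentage points on curved segments). The reference is the median
diameter over the stations: the focal dip spans a small fraction of the
segment, so the median tracks the nominal caliber the way a distal
reference does without being contaminated by the junction ends. Accuracy is
voxel-limited: about one voxel of uncertainty on the waist diameter, i.e.
100·spacing/d_ref percentage points (7.5 points for the 4 mm ICA at
0.3 mm spacing); the tests assert recovery within exactly that bound.

**Grading.** normal (0 %), mild (≤29 %), moderate (30–69 %), severe
(≥70 %); fractional values between 29 and 30 are rounded to the nearest
integer band first.

## Variant classification and statistics

A ring segment is a variation when not visualized, or when its diameter is
strictly less than 0.3× the contralateral homologue ("over 70 % thinner"
read as exceeding 70 %). An Aco is exempt when the bilateral ACAs are
fused. Anterior completeness requires Aco + both A1 normal; posterior
requires both Pco + both P1; the entire circle requires both parts.
Bilateral families are reported per patient as "variation on either side"
(the convention that reproduces published prevalence tables); a per-side
convention is available as an option.

Published tables print only group size and integer percent prevalence.
Counts are reconstructed by half-up rounding of n·pct/100, with a warning
when the count does not round-trip to the printed percentage. Group
comparisons use Pearson's chi-square on the 2×2 table without Yates
continuity correction (the uncorrected statistic reproduces all six
published p-values at printed precision; the corrected one does not), df=1,
two-sided, and deliberately without multiple-comparison adjustment,
matching the source analysis. Continuous summaries are compared with a
two-sample t-test from summary statistics (pooled variance by default,
Welch optional).

## Numerical and degenerate-case choices

* Dice loss ε = 1e-6 in numerator and denominator; both-empty → 0 loss.
* Both-empty evaluation Dice = 1.
* Chi-square with a zero margin raises rather than returning NaN.
* Zero-variance t-test: equal means → p = 1; unequal means raises.
* measure_stenosis on an empty or occluded lumen returns 100.
* Mask rasterization is centre-in-tube (exact); intensity uses 3× per-axis
  supersampled occupancy.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec/config objects; two runs with the same seeds are bit-identical.

## Known limitations

* The phantom's geometric realism is intentionally minimal; absolute Dice
  values on phantoms say nothing about clinical data.
* Bright tubular phantom vessels leave little generalization gap: both
  model variants converge to high, nearly identical held-out Dice at every
  difficulty setting tried, so the multitask-versus-single-task comparison
  operates within its noise band at this scale. The multitask advantage is
  a claim about hard, label-scarce clinical data; the desk-scale experiment
  asserts the ordering and honestly reports when it does not resolve.
* The 2D slice-wise model never sees 3D context; through-plane vessels are
  easier on phantoms than in practice.
* The detection surrogate and the EDT diameter estimator are package
  definitions — precise and reproducible, but not clinically validated.
* Batch-norm inference uses running statistics accumulated over a short
  schedule; with very few training steps they can lag the batch statistics.
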