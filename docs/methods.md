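# Methods

`ifcmrd` implements a label-free residual-disease (MRD) monitoring pipeline
for childhood B-lineage acute lymphoblastic leukemia (ALL), built around
imaging flow cytometry (IFC): each cell is recorded as a 12-channel image
stack (two bright-field channels, one dark-field channel acting as a
side-scatter surrogate, and fluorescence channels for CD10, CD34, DAPI,
CD19, CD45 and a non-discriminative FITC control), at 40x magnification
and 0.3 um pixels.  A residual convolutional network classifies each
in-focus single cell as *leukemic blast*, *normal B lymphocyte* or *other
nucleated cell*; the per-sample MRD fraction is the percentage of
predicted leukemic cells among all evaluated cells, and the clinical
readout is the sample-level call at a fraction cutoff (25% marks slow
early responders).  The headline property of the approach is that the
classifier works from the two label-free channels (bright-field +
dark-field) alone.

Because clinical IFC data cannot ship with the package, every stage is
exercised against a synthetic generator whose statistical structure
matches the pipeline's assumptions.  All results the test-suite and the
acceptance script report are computed on that generator.

## Synthetic cell generator

Each cell is a disc with a radial bright-field profile (darkened interior,
darker nucleus, bright rim), band-limited intracellular texture
(Gaussian-filtered white noise at a class-specific grain), and a
dark-field plane of Poisson-placed speckles whose density is the
side-scatter surrogate.  Backgrounds are constant offsets plus Gaussian
noise per channel; the outermost 3-px frame of every image is pure
background, which downstream padding relies on.  Fluorescence channels add
a log-normal per-cell amplitude inside the cell mask (nucleus mask for
DAPI) when the acquisition is stained *and* laser-on; otherwise they carry
detector noise only.  Bright-/dark-field pixels are drawn from a random
stream separate from the fluorescence stream, so the label-free content of
a cell is bit-identical across the four stained/unstained x laser-on/off
acquisition arms (up to an optional bleed-through term that adds a
fraction of the summed fluorescence into the bright-field planes).

Class-conditional defaults (documented constants in
`synthetic.default_phenotypes`):

| class    | radius (px)  | nucleus ratio | texture grain | DF speckles /100 px^2 | markers |
|----------|--------------|---------------|---------------|------------------------|---------|
| leukemic | 10.0 +- 0.7  | 0.75          | 1.0           | 3.0                    | CD19+ CD10+ CD34 broad CD45 broad |
| normal   | 6.5 +- 0.7   | 0.80          | 2.2           | 0.8                    | CD19+ CD10- CD34- CD45+ |
| other    | 14.0 +- 1.0  | 0.55          | 1.6           | 12.0                   | CD19- DAPI+, high DF |

Radius means sit >= 3 sd apart, so class identity is recoverable from the
label-free channels (a nearest-centroid classifier on radius + dark-field
speckle count exceeds 95% accuracy; the suite asserts this, guarding
against a degenerate generator).  Positive and negative marker amplitudes
are >= 10x apart, so sequential gating recovers the generating class on
>= 99% of clean cells and can serve as a truth oracle.  Biologically the
ordering is deliberate: normal B precursors are small and smooth, blasts
larger with finer chromatin, and the "other" pool (granulocytes,
monocytes) largest and speckle-rich.  Per-patient heterogeneity is a small
deterministic jitter (sd 0.15 px) of the radius means.

Contaminants: *clumps* are two same-class discs whose centers sit at
60-90% of the summed radii; *out-of-focus* events are whole-stack Gaussian
blurs (sigma 2.5 px).  Contamination defaults to 2.5% + 2.5%.

What the generator does **not** emulate: physical optics (diffraction,
depth of field), spectral spillover structure, camera-specific noise, cell
shape irregularity, or biological continua between classes.  Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its statistical procedures behave as designed — not that the
classifier would reach the same accuracy on patient data.

## QC and sequential gating

Event QC reproduces the instrument-side exclusions with three measures on
the first bright-field channel: object area, aspect ratio (minor/major
axis from the mask's second moments), and the gradient-RMS focus score
over the cell region.  Segmentation is a global threshold on the
smoothed absolute deviation from the median intensity — Otsu's threshold
capped at 3.2x the median deviation, since Otsu alone lands mid-way up the
cell's contrast range and clips the low-contrast band inside the rim —
followed by hole filling and largest-component selection.  On rendered
discs of radius 10 px the measured area is within a few percent of
pi r^2.

No numeric cutoffs exist in print for this instrument class; the defaults
(area 60-1000 px^2, aspect >= 0.76, gradient RMS >= 6.5, DAPI >= 40) were
calibrated once against the generator's default phenotypes and are
ordinary overridable constants.  At those defaults >= 95% of contaminants
are rejected and <= 5% of clean cells are lost, and the suite asserts
both margins.

The gating tree mirrors the expert protocol: DAPI- events are
red-cell/debris; DAPI+ events that are CD19- or dark-field-high are
"other"; CD19+ CD10+ cells are leukemic irrespective of CD34/CD45 (the
leukemia-associated immunophenotype is CD34+/- CD45+/-); CD19+ CD10- CD34-
CD45+ cells are normal B lymphocytes; remaining CD19+ cells fall back to
"other".  Whether ground-truth "other" additionally required CD19
positivity is ambiguous in the source protocol; this tree accepts both
CD19- and CD19+ high-scatter cells into "other".  The clinical
sample-positivity rule is implemented verbatim: positive iff the leukemic
fraction is >= 0.01% *and* >= 50 events cluster.

## Preprocessing

Training chain: canvas -> contrast stretch -> zero-center -> augment;
inference chain stops at zero-center (never augments).  Canvas
standardization center-crops larger images and pads smaller ones with
noise drawn from the image's own 3-px border frame — the per-image reading
of background-noise padding; a dataset-level background pool would be the
alternative and is intentionally not used.  Contrast stretch maps each
channel's [0.5, 99.5] percentile band (linear-interpolation percentiles,
the most common convention) onto {0..255} by v' = floor(256 * clip((v -
q_lo)/(q_hi - q_lo), 0, 1)) capped at 255; constant channels map to zero
with a once-per-role warning.  Channel means for zero-centering are
computed on the training partition only and stored with the model, so the
same means are subtracted at test time.  Augmentation draws horizontal /
vertical flips, integer shifts up to half the side, and rotations uniform
in [-180, 180] degrees; rotation+shift run through a single bilinear
affine transform whose out-of-support pixels are filled with border-frame
noise (consistent with canvas padding — reflection or constant fill are
the unstated alternatives).  Because floor quantization lets a second
stretch's percentile band shrink slightly, re-stretching can move a pixel
by up to ~2 grey levels on noisy images (1 on smooth ramps); the suite
pins this.

## Partitioning and balancing

Records of held-out patients go entirely to test; remaining cells are
split 80/20 into train/validation at the cell level, stratified by
(patient, class) so no desk-scale validation fold loses a class (the
source protocol says only "randomly"; stratification is this package's
choice).  Balancing undersamples each patient's present classes to that
patient's minimum class count, without replacement.  Patient-disjointness
of train/validation vs test is asserted at split construction and again at
the start of every training run.

## The classifier

Two presets.  `small` (default): an 8-convolution residual network —
stride-2 3x3 stem to 24x24, max-pool to 12x12, then conv/residual-block
stages widening 12 -> 16 -> 32 -> 64 with batch normalization after every
convolution, global average pooling to a 64-wide embedding and a softmax
head.  `resnet50`: the standard bottleneck architecture (stages 3/4/6/3,
2048-wide pooled embedding) for parity with the full-scale model; it
builds and runs forward on CPU but is not the test default.  Architecture
depth is a configuration knob, not a study subject.

The engine is a compact numpy implementation (im2col convolutions over
BLAS matmul, manual backprop, Adam); the im2col/col2im memory shuffles
are numba-jitted when numba is present (serial loops — no change in
results), and per-image augmentation warps run as one vectorized bilinear
gather per batch.  The whole path is single-threaded and free of
nondeterministic reductions, so training is bit-reproducible given the
seeds.  Zero-centered uint8-scale inputs are divided by a fixed 128 inside
the model and the softmax head uses a small (sd 0.01) initialization —
architecture constants that keep initial activations and logits O(1).

Training schedule: categorical cross-entropy, Adam at learning rate 1e-4,
batch size 256, ceil(M/256) steps per epoch (ceiling, so the full training
set is seen each epoch), live augmentation on the training *and*
validation streams, validation once per epoch on the full validation set,
learning rate x0.1 after 10 epochs without validation-loss improvement,
early stop after 25, cap 512 epochs, best-validation-loss weights (and
batch-norm running statistics) restored at the end.  "Improvement" means a
decrease exceeding 1e-4 absolute, so float jitter cannot reset patience.
On a constant-loss trace the schedule provably steps the learning rate at
epoch 11 and stops at epoch 26; the suite replays this rule offline
against recorded histories.

One desk-scale caveat: with Adam the per-parameter step is bounded by the
learning rate, so what limits convergence at a fixed 1e-4 is the total
number of update steps, not the number of epochs.  Full-scale cohorts
provide hundreds of steps per epoch; a 1,500-cell cohort at batch 256
provides five.  Small cohorts therefore train with a smaller batch (64 in
the suite's training test) so an epoch cap in the dozens still gives the
optimizer enough steps — batch size is the one schedule field treated as
scale-dependent.

Prediction applies no augmentation, uses stored training means, and breaks
probability ties toward the class earliest in the label ordering
(leukemic < normal < other lexicographically).

## Desk-scale benchmark

The reference protocol (`benchmark.run_benchmark`) trains on 4 synthetic
patients of 900 cells each (balanced per patient to roughly 290 cells per
class; ~2,700 training and ~700 validation cells after the 80/20 split)
and evaluates 12 held-out samples of 2,000 cells whose true leukemic
fractions are {2, 5, 10, 15, 20, 22, 30, 35, 40, 55, 70, 80}% — six on
each side of the 25% cutoff, including near-boundary samples at 20-22 and
30%.  The epoch cap is 40: on cohorts this size the synthetic classes
separate within a few dozen epochs, not the hundreds the full-scale
schedule allows for, and the plateau/early-stop rules remain active below
the cap.  Both the label-free ({BF1, BF2, DF}) and the all-channel
(12-plane) models train with identical seeds and schedule and are scored
on the same cells.  Reported quantities: sample-level sensitivity and
specificity at the 25% cutoff (strict '>' on both prediction and truth —
a sample at exactly 25.0% is *not above threshold*; '>=' is the
alternative reading and is configurable), pooled per-cell 3-class
accuracy, and per-sample predicted-vs-true fractions.

## Classical arm

Segmentation reuses the bright-field mask.  The native extractor computes
~100 features per cell: per-channel intensity statistics inside the mask
(mean/median/sd/MAD/quartiles), size-shape (area, Crofton perimeter, form
factor 4 pi A / P^2, aspect ratio, eccentricity, solidity), co-occurrence
texture (contrast/homogeneity/entropy at 1-2 px offsets, 8 grey levels,
bright-field and dark-field), gradient RMS, and pairwise inside-mask
channel correlations.  It replaces a full high-content platform by design;
feature-level parity with any particular tool is a non-goal.

Feature selection runs three sequential filters and reports every drop
with its rule: (1) near-zero variance — variance relative to the squared
value range below 1e-4; (2) poor correlation across replicates — mean
Pearson correlation of per-group median profiles across replicate pairs
below 0.5 (replicate groups for synthetic data are independent same-spec
samples); (3) greedy redundancy pruning over the |r| > 0.95 graph,
retaining per connected component the feature with the best replicate
correlation (ties: first by name).  Afterwards no retained pair exceeds
|r| = 0.95 (brute-force verified in the suite) and the procedure is
idempotent.  The two numeric thresholds in (1) and (2) are declared
defaults, not published values.

The comparison classifier standardizes features with training statistics
and fits a linear SVM whose regularization strength C is chosen by
randomized log-uniform search (1e-3..1e3) on a held-out validation fold;
a leave-one-patient-out helper evaluates it across patients.  Note that
on synthetic discs the hand-crafted features capture the generative
factors (size, granularity) almost perfectly, so the classical arm is
*not* expected to trail the CNN here the way it does on real imagery —
comparisons between the two arms on synthetic data say little about
their relative merit on patient samples.

## Embedding exploration

Penultimate-layer embeddings (64-wide for the small preset, 2048 for
resnet50) or classical features are projected with t-SNE (perplexity 30,
>= 400 iterations, seeded) or PCA (deterministic; each component's
largest-magnitude loading is made positive) and exported as the
vectors/metadata TSV pair standard embedding projectors consume.  Rows are
never reordered.

## Numerical and degenerate-input choices

- Coordinates are row-major, origin top-left, 0-based, half-open slices.
- An empty segmentation mask yields area 0 and a flag, never an exception;
  blank images are "unsegmentable" in the classical arm.
- Constant channels stretch to all-zero with a warning.
- Probability rows sum to 1 within 1e-5 (float32 softmax).
- All randomness flows from named integer seeds through
  `numpy.random.Generator` spawning; identical seeds give bit-identical
  cohorts, training runs and reports.

## Known limitations

- The CNN engine is CPU-bound numpy; it is sized for desk-scale cohorts
  (thousands of cells), not the millions a clinical deployment would see.
- The generator's class separation is a controlled dial; real morphological
  overlap between blasts and normal B precursors is certainly larger, so
  synthetic accuracies bound the machinery, not clinical performance.
- Vendor .CIF/.RIF/.DAF containers are not parsed; data enters through the
  open TIFF+TSV container or any adapter that yields `CellRecord`s.
- Spectral compensation is out of scope; bleed-through is modelled as a
  single scalar coefficient into the bright-field planes.
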