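# Methods

## Scope and model

manoflow treats one wet swallow per 60-s high-resolution manometry (HRM)
recording. The physical object is a 36 × 600 pressure matrix (36 sensors,
10 Hz, mmHg); everything downstream — IRP measurement, rendering,
preprocessing, classification — consumes either that matrix or the raster
rendered from it.

### IRP definition

The integrated relaxation pressure is defined on the e-sleeve trace, the
per-sample maximum across the esophago-gastric-junction (EGJ) sensor
range. The maximum is the standard e-sleeve convention: it emulates a
sleeve sensor reporting the tightest point of the sphincter regardless of
small axial catheter movement. Within the 10-s window anchored at the
swallow marker, the IRP is the mean of the k = round(4·fs) smallest
samples. Because the "lowest 4 s" may be non-contiguous, no contiguity
constraint applies and the computation is a pure order statistic; it is
bounded below by the window minimum and above by the window mean, and it
is monotone in every input sample (both properties are tested). The window
is anchored at the marker itself; detecting upper-sphincter relaxation to
anchor the window is out of scope. The 28 mmHg cut-off is an *upper normal
limit*, so equality classes as normal.

## Synthetic recordings

No public HRM image corpus exists, so the simulator is a first-class
module that defines the study conditions. It emulates the features the
downstream stages depend on, with defaults fixed once:

- **Bands.** Upper-sphincter band at sensors 0–1 (40 mmHg), esophageal
  body baseline 10 mmHg (sensors 2–29), LES band at the EGJ sensors 30–32,
  gastric baseline 5 mmHg at sensors 33–35 (the acquisition protocol
  requires at least three sensors in the stomach; gastric pressure is the
  manometric reference).
- **Swallow.** The marker time is jittered uniformly in 27–33 s, matching
  the acquisition convention of saving screens with the wet-swallow mark
  near mid-image. LES relaxation is a raised-cosine dip starting at the
  marker: resting 30 → nadir 5 mmHg over 8 s for the normal-IRP scenario
  (IRP ≈ 10 mmHg), resting 35 → nadir 33 for the high-IRP scenario
  (IRP ≈ 34 mmHg). The raised cosine is smooth and parameterized by depth
  and duration only; no claim of physiological waveform fidelity is made.
- **Peristalsis.** A Gaussian pressure ridge (peak 80 mmHg, σ = 1.5 s)
  sweeps the body sensors proximal→distal at 3 cm/s starting 0.5 s after
  the marker. At 1 cm sensor spacing it reaches the distal body ~9.5 s
  after the marker, so it never contaminates the EGJ e-sleeve within the
  IRP window.
- **Positioning failures.** `failure_mirror` reflects the built field
  about the distal EGJ edge so a duplicate high-pressure band appears
  below the EGJ (a folded/coiled catheter); the mirrored band correlates
  >0.9 with the EGJ band by construction plus independent noise.
  `failure_no_les` replaces the LES band with body baseline (catheter not
  across the sphincter). Both are literal encodings of the qualitative
  failure appearance; no quantitative clinical description of such images
  exists to calibrate against.
- **Noise.** Additive Gaussian, sd 1.5 mmHg, truncated at 0 for the
  body/EGJ/gastric channels (the reference cannot read negative there);
  the whole matrix is clipped to [−20, 300] mmHg.
- **Ground truth.** The per-swallow true IRP is *defined* as the IRP
  engine's output on the generated matrix over the true EGJ range, so
  recovery is exact by construction; the separation of the two IRP classes
  across seeds (normal ≤ 28, high > 28 on every draw) is the tested
  property.

The sampling rate (10 Hz) and spacing (1 cm) are package choices — the
acquisition rate of the original instrument is not public — picked so the
10-s IRP window holds exactly 100 samples.

What the simulator does **not** emulate: achalasia subtypes or any other
specific diagnosis, multiple swallows per recording, respiratory and
vascular artifacts, text overlays on the instrument screen, or the
proprietary instrument palette. Passing tests therefore demonstrate the
*mechanism* — rendering, ROI extraction, training, evaluation — at desk
scale, not clinical performance on real images.

## Rendering

The raster is 1000 × 600 px with grey margins of 15 px (top), 120 px
(left), and 30 px (bottom) — exactly the margins the preprocessing strips
— leaving a 880 × 555 plot area. Sensors map to rows top-down
(proximal→distal) and time maps affinely to columns; resampling is
nearest-neighbour so band edges stay crisp. The wet-swallow marker is a
1-px pure-white column drawn without antialiasing, giving the white-pixel
histogram a unique maximum.

The color scale is a hand-built jet-like piecewise-linear RGB map over
[−10, 150] mmHg with one engineered property: its Rec. 601 luma crosses
the 128 binarization threshold exactly once, upward, near 24 mmHg. Hence
binarization keeps the LES band (≥ ~28 mmHg), the peristaltic ridge, and
the marker, and discards the gastric/body baselines; the set of "white"
pressures is upward-closed, and the map's maximum luma (≈226, yellow)
stays below the marker's 255. A stock jet colormap does not have this
property (it maps ~30 mmHg to luma < 128), which is why the scale is
built by hand.

## Preprocessing

The five steps run in fixed order: strip margins → binarize → column
histogram → argmax → crop. Decisions that the verbal rule leaves open are
fixed as: grey level = Rec. 601 luma computed with integer weights
(299/587/114 over 1000) so an exact grey of 128 sits *on* the inclusive
threshold; argmax ties break to the smallest x; coordinates are 0-based,
origin top-left, inclusive intervals. The IRP ROI is located on the
binarized swallow crop at original scale (before any resize): the lowest
white pixel anchors a 100-px band extending upward, clamped at the top
edge; a clamped band is zero-padded back to 100 rows so the model-input
geometry is stable. Because the marker column reaches the plot bottom, the
band is in practice the bottom 100 px of the crop, which covers the LES
band and the gastric band beneath it — the region whose color dynamics
encode sphincter relaxation. Model inputs are bilinear-resized to
299 × 299 and mapped v → v/127.5 − 1.

No deskewing, denoising, or robustness to extra white overlays is
attempted; an all-black binarized image raises a detection failure rather
than guessing.

## Classifiers

Both tasks use a frozen feature extractor and a trainable head of global
average pooling → dropout 0.20 → dense 2-unit softmax, trained with Adam
(lr 0.01, β₁ 0.9, β₂ 0.999), batch 32, reshuffling every epoch. The
positioning model consumes the full swallow crop; the IRP model consumes
the 100-px band. The default backbone (`small_cnn_fallback`) is three
3×3 convolutions (16/32/64 channels, ReLU, two 4× max-pools) with fixed
seeded He-initialized kernels; it is frozen, downloads nothing, and makes
every run deterministic on one CPU. The ImageNet-pretrained InceptionV3
backbone is available behind the same interface when a tensorflow runtime
is installed; the backbone is frozen in either case (a config flag exists
to unfreeze, but pure feature extraction is the default and the tested
path). Features are z-scored on the training set before the head; dropout
is the inverted variant so inference needs no rescaling.

Splitting is stratified 70/15/15 with floor rounding per class and seeded
in-class shuffling: a class of n items contributes ⌊0.70n⌋ / ⌊0.15n⌋ /
remainder. The 15% "test" part provides intermediate feedback — its loss
and accuracy are logged after every epoch and drive early stopping
(patience 5, best-test-loss weights restored; default 20 epochs). The
validation part is never read during training — the training routine only
touches the train and test members — and exists solely for the final
evaluation.

Epoch count, learning rate, and early stopping are package choices (the
protocol source states optimizer, batch size, and shuffling only). No
data augmentation is used anywhere: for positioning failures the spatial
arrangement itself is the signal, so augmentations that move, scale, or
flip the image would corrupt labels.

## Evaluation

Per-class precision, recall, and F1 plus overall accuracy are computed
from the 2×2 confusion matrix (rows = truth, columns = prediction) at full
precision and displayed as whole percents rounded half-up — half-up
reproduces every derivable printed table value of the reference tables. A
zero-denominator metric is reported as 0 with an explicit flag instead of
NaN. The positive class is task-dependent (correct positioning; normal
IRP) and recorded in the report.

## Problem sizes

The test suite trains the end-to-end IRP classifier on 200 synthetic
images per class (280 training / 60 test / 60 validation items after the
split) and checks ≥90% validation accuracy; the acceptance script repeats
this and additionally measures the IRP sorting-oracle agreement on 1000
random traces and marker recovery on 100 renders. These sizes exercise
every mechanism at desk scale; larger runs only change runtime.

## Known limitations

- Synthetic images are far cleaner than instrument captures: classifiers
  reach ~100% on them, which validates the pipeline mechanics, not
  clinical accuracy.
- The mirror/no-LES failure generators encode a verbal description; real
  positioning failures are more varied.
- Real captures may contain white text overlays that would perturb the
  projection-profile marker detector; robustness to them is untested.
- The full Chicago Classification beyond the IRP branch is out of scope.
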