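# Methods

This note documents the models, the parameter choices, the synthetic
data the package is validated on, and the limits of what those
validations show.

## Pipeline model and assumptions

The pipeline assumes a single, roughly frontal subject per video whose
expression changes on the timescale of seconds while the head undergoes
moderate rigid motion (scale 0.8–1.2×, in-plane rotation within ±15°,
out-of-plane rotation within ±20°, translation within ±20 px at QVGA).
Classification is purely per frame — no temporal smoothing and no
randomness anywhere in inference, so identical inputs give bit-identical
outputs.

**Colour and cropping.** RGB frames are converted to YCbCr with the
full-range (JFIF) matrix; the luma plane drives everything downstream.
Face localisation is a deterministic brightness-blob detector: Otsu
threshold on luma, morphological closing (disk radius 2) so thin dark
creases cannot split one face into two components, connected-component
labelling, and the largest region with a face-plausible aspect ratio
(0.6–2.2) and fill fraction (≥ 0.35). An override hook accepts an
externally supplied box, which annotated training data uses as a
fallback. Crops are bilinear-resized to 64×64. The shot filter keeps a
frame when a face was found and the crop's 3×3-Laplacian variance is at
least 10 (8-bit intensities); both predicates are cheap and idempotent.

**Point operations.** The enhancement operates on intensities
normalised to [0, 1]: `s = c·log(1+r)` (natural log, default `c = 3.5`)
or `s = c·r^γ` (defaults `c = 3, γ = 2`), then rescales by the curve
maximum (`c·log 2` resp. `c`) back to [0, 255] with round-half-up. A
consequence of this normalise-and-rescale convention is that the final
8-bit image is independent of `c` — the constant shapes the curve only
before rescaling. The convention is kept because it guarantees
displayable output for any parameter value; `c` remains a configuration
key. Default mode is the log transform; `exp`, `none` and
`sharper` (run both, keep the higher-Laplacian-variance result) are
selectable.

**Landmark model.** The 66-point layout is jaw 0–16, brows 17–26, nose
27–35, eyes 36–47, mouth 48–65. Generalised Procrustes alignment
(centre, unit Frobenius norm, rotate to the evolving mean, tolerance
1e−8) precedes PCA; the shape model keeps the smallest number of modes
reaching 95% of variance. The appearance model (mean plus top-l
eigenimages, default l = 5) is built from crops piecewise-affine-warped
onto the base mesh; it validates the training data and is not used
inside the fitting loop, which is driven by the patch and shape models
alone. Patch templates are 11×11, zero-mean unit-variance, averaged over
the peak training frames. Tree connectivity is the Euclidean minimum
spanning tree over visible landmarks, built with Kruskal's algorithm on
edges sorted by (weight, i, j) so ties break toward lower indices.

**Fitting.** Each iteration computes, for all 66 landmarks at once,
normalised cross-correlation response maps in a 15×15 search window
(integral-image box sums), moves each point to the centroid of the
positive responses squared, then projects the shape onto the PCA
subspace with each coefficient clamped to ±3√eigenvalue — so any fitted
shape is statistically plausible by construction. Iteration stops at a
mean displacement below 0.1 px or after 20 rounds; a landmark is flagged
invisible when its response peak falls below 0.3. Tracking initialises
each frame from the previous frame's fit.

**Pose features.** A canonical 3-D version of the 66-point template
(authored coarse depths: nose forward, cheeks receding) is fitted to the
observed 2-D points under weak perspective: least-squares affine camera,
SVD orthonormalisation, Euler decomposition `R = Rz(roll)·Ry(yaw)·Rx(pitch)`.
Scale is the ratio of fitted scales against the reference shape, shifts
are centroid differences. One unified 3-D fit is used for all four
rotational/scale quantities because it reduces exactly to the 2-D
similarity fit when yaw = pitch = 0 and stays consistent out of plane;
on noiseless generator output the recovery is exact to numerical
precision.

**Texture descriptor.** The 9-bin LBP histogram bins each interior
pixel's 8-neighbour code (neighbour ≥ centre counts 1, so ties count) by
its number of set bits. Two properties matter: it is invariant to any
strictly increasing intensity remap, and its extreme bins (0 and 8)
essentially count local intensity maxima and minima — the histogram is
mostly a local-extrema-density summary, which is what the synthetic
renderer is designed around (below).

**Classifier.** The 6 pose + 9 LBP values are z-normalised per dimension
(statistics over all training peak frames, std floor 1e−6) and fused
into one 15-vector; each class template is the mean descriptor of its
peak frames. At test time `diff` is the Euclidean distance between the
frame's descriptor and the neutral reference *evaluated at the current
pose*: the reference's six pose components track the current frame
(global head pose is expression-independent nuisance and never counts as
deviation), while its nine texture components always compare against the
trained neutral texture, so the reference can never adopt a pain or
other-expression appearance. Designs in which the reference adopted
recent peak frames were tried and rejected: adopting a pain peak makes
subsequent pain frames look neutral, adopting a not-pain peak dilutes
the pain margin, and refreshing pose only at peaks produces distance
spikes at expression transitions.

**Threshold calibration.** Candidates are pooled *and per-class*
quantiles of the training distances at 1% spacing (pooled-only grids can
skip the empty margin between classes entirely); the pair (Δ1, Δ2)
maximising macro-averaged per-class accuracy wins, ties broken by
smaller Δ1 then smaller Δ2; finally each threshold is re-centred in the
empty interval between its adjacent training distances — the training
confusion is unchanged but the cut sits mid-gap instead of on a data
point, which generalises better. Boundary equalities always fall to the
severer class, so a tie can never miss pain. Calibration is two-pass:
static-template distances seed the thresholds, then the streaming
procedure used at test time supplies the distances for the final
calibration. If the best achievable macro accuracy is near chance the
calibration logs a warning.

**MLBPNN.** The comparison network is 15 → 2 → 1 → 2 → 3 (three hidden
layers, five nodes total, as configured by default), sigmoid hidden
units, softmax output, cross-entropy, full-batch gradient descent with
classical momentum (learning rate 0.5, momentum 0.9), seeded
initialisation, 80/20 train/validation split and early stopping
(patience 50) that is suppressed for the first 250 epochs — the one-node
bottleneck sits on a loss plateau for on the order of a hundred epochs
before its units differentiate, and naive early stopping halts there at
chance accuracy. The layout is an escape-hatch config key.

**Evaluation.** HR = pain frames labelled pain / true pain frames;
FAR = non-pain frames (neutral and not-pain pooled) labelled pain /
non-pain frames. ROC sweeps the pain threshold over the per-frame
distances (scikit-learn's sweep; AUC trapezoidal). The per-GOP HR range
reports min and max window-level HR over consecutive 15-frame windows
that contain at least one true pain frame.

## The synthetic generator

The generator emulates the study conditions this kind of system is
developed under: per-video expression segments (neutral, pain, and one
of smile/surprise/angry) of 30–50 peak frames each, smooth random-walk
rigid head motion within the ranges quoted above, illumination gain
walking in [0.4, 1.2], additive Gaussian sensor noise (default σ = 2),
expression amplitude (default 0.9) scaling hand-authored displacement
fields on the 66-point template. Every frame carries ground-truth
landmarks, class label and pose, which enables exact parameter-recovery
tests.

Renders are deliberately schematic, but their *texture statistics* are
designed so that the popcount-LBP descriptor can register expressions,
mirroring (in stylised form) how real faces behave:

- every surface has stable micro-structure (a face-anchored skin
  texture, a patterned backdrop) with gradients well above the noise
  floor, so flat-region LBP codes are deterministic rather than
  noise-random;
- open eyes carry a bright sclera, a dark pupil and an iris speckle row
  — dozens of strong local extrema that vanish entirely when a pain
  grimace squeezes the orbits shut (the squeezed lid renders as a beaded
  lash line);
- a pain grimace additionally tenses the skin into finer, stronger
  stipple and deep furrow strokes (glabellar, brow, nasolabial, cheek,
  chin) — the densest texture signature of any expression;
- smile raises the mouth corners and reveals a bright tooth band;
  surprise raises the brows, widens the eyes and drops the jaw (dark
  oral cavity); angry knits the brows with glabellar creases.

Structure sizes are chosen in face-relative units so they survive the
resampling to the 64×64 crop at any face scale in the motion range.

What the generator does **not** emulate: photorealistic skin and
illumination (shadows, specularity), occlusions by hands or glasses,
multiple subjects, identity variation beyond rigid/expression motion,
compression artefacts, and expression intensity dynamics within a
segment (amplitude is constant per segment). Passing the end-to-end
tests therefore demonstrates that the pipeline's machinery — detection,
enhancement, model building, fitting, features, calibration,
classification, evaluation — is internally correct and deterministic
under controlled nuisance factors; it does not demonstrate clinical
accuracy on real faces.

## Problem sizes

The full synthetic study (tests and `scripts/acceptance.py`) uses 22
training videos and 4 held-out videos of 135 frames each (three
45-frame segments), QVGA resolution, amplitude 0.9, noise σ = 2 — about
3,500 frames end to end. Unit tests use shorter sequences (tens of
frames) of the same kind. The MLBPNN fixture is 300 points in 15
dimensions, three collinear Gaussian clusters five standard deviations
apart.

## Numerical choices and degenerate inputs

Round-half-up after every intensity rescale; Procrustes tolerance 1e−8;
PCA via SVD of the centred data matrix; eigenvalue floor 1e−12 of total
variance for retained modes; patch normalisation guards zero-variance
patches; NCC denominators floored at 1e−9; std floor 1e−6 in feature
normalisation. Degenerate cases: all-coincident landmark shapes raise an
alignment error; identical training shapes give a zero-mode model (the
mean); a missing training class raises an error naming the class;
constant training distances trigger the quantile fallback Δ1 = q33,
Δ2 = Δ1 + ε with a warning; an empty frame sequence classifies to an
empty result list; a video in which no face is ever found yields empty
results and a warning, not an error.

## Known limitations

- The blob-based face localiser is designed for the generator's
  bright-face-on-dark-background renders; real footage would need a
  learned detector behind the same `detect_and_crop_face` interface
  (the override hook and the bbox-injection hook are the seams).
- Pose features from a monocular weak-perspective fit are exact on
  generator output but biased on strongly non-rigid expressions
  (deformation leaks into pitch/scale).
- The pain/not-pain margin rests on texture statistics; expressions
  whose texture signature resembles the pain stipple would erode it.
- Video-container decoding requires an imageio plugin with ffmpeg
  support; frame folders and the live frame-source protocol are the
  always-available inputs.
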