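# Methods

`gaitheel` implements a two-step, marker-less pipeline for extracting heel
contact points — and from them step length and step width — from video
recordings of walking (e.g., Timed Up and Go tests filmed at 25 Hz from the
side and the front).

1. **Coarse step.** A general-purpose pose estimator (consumed via its
   25-keypoint JSON output; never re-implemented here) provides noisy
   whole-body keypoints per frame. These are accurate enough to (a) find
   the parts of the video containing gait, (b) approximate heel-strike
   events, and (c) locate the feet in the image.
2. **Fine step.** At heel-strike frames, a fixed 160x120 crop around the
   foot (centered on the centroid of the ankle, big-toe and heel keypoints)
   is fed to a dedicated convnet that predicts the *heel keypoint*: the
   most posterior point of the heel in contact with the floor (side view)
   or the most lateral such point (frontal view). Because this point lies
   on the floor plane by definition, a planar homography calibrated from
   marked floor points converts it to metric floor coordinates from a
   single camera.

## Floor calibration

`estimate_homography` uses the normalized DLT: Hartley normalization of
both point sets (zero centroid, mean distance sqrt(2)), SVD null vector of
the 2n x 9 system, de-normalization, and scaling to `h[2,2] = 1`. At least
four image/floor correspondences are required; five to eight marked points
is typical. No nonlinear refinement is applied — for hand-marked floor
points the algebraic solution is already at the marking accuracy, and for
noiseless synthetic scenes it is exact (recovery to ~1e-12, round-trip
projection to ~1e-9 in the tests). Floor coordinates are centimeters: x
along the walking axis, y to the left of it.

Degenerate configurations (collinear marks) are detected from the
second-smallest singular value of the DLT system and rejected.

## Event detection

The heel strike is approximated by the frame at which the absolute
heel-to-heel image distance peaks: at landing, the feet are maximally
apart. The distance series is interpolated over frames where either heel
is undetected, smoothed with a centered moving average (default window 3
frames), and peaks are picked by prominence (default 5 px) with a minimum
separation (default 10 frames = 0.4 s at 25 Hz, below any plausible step
time). Peaks closer than the separation are pruned greedily by height,
the earlier frame winning exact ties. The defaults are configurable
because the reference workflow corrected events by visual inspection and
published no peak-picking parameters.

Gait intervals are frames where the smoothed forward heel velocity exceeds
a threshold (default 25 px/s) for at least 0.5 s; this separates walking
from sit-to-stand and turning without attempting full activity
recognition.

## Dataset handling

Labels are integer-pixel heel coordinates inside the 160x120 crop.
Augmentation follows the corpus recipe: 20 random translations of the
crop window per image, each axis drawn independently and uniformly from
the integers [-30, 30] ("a 60-px-wide uniform distribution"), plus a
horizontal flip of every translated image — a 40x multiplier (4,824 side
originals -> 192,960; 2,756 frontal originals -> 110,240; the published
corpus sizes). Translations re-crop from the source frame, so no synthetic
padding statistics enter the training data; a window that would leave the
frame falls back to edge replication with a logged warning. Flips are
horizontal only, since left and right feet mirror each other. Splits are
by subject (the study used 157/9/18 of 184), so augmented copies can never
leak a subject across train/validation/test.

## Models

Six variants: three ImageNet-class backbones (VGG19, ResNeXt-50 32x4d,
MobileNetV2, reproduced layer-for-layer; their classifier trims match the
published parameter counts exactly) crossed with two heads:

* **Regression head**: the full backbone including its 1000-way output,
  plus a fully connected 1000 -> 2 layer (2,002 parameters) emitting the
  heel's normalized crop coordinates (x/160, y/120), denormalized by the
  crop size at prediction time. No squashing nonlinearity is applied; a
  trained model emits values in [0, 1] on in-distribution crops.
* **Heatmap head**: the backbone's feature-extraction layers only (VGG19:
  its 16 convolutional layers; the others: everything before global
  pooling; output stride 32), then five transposed-convolution layers
  (kernel 4, stride 2, padding 1, each followed by batch normalization and
  ReLU) and a final 1x1 convolution to one channel. From a 120x160 input
  the response map is 128x160 (96x160 for VGG19), "similar to" the input
  resolution. The channel schedule of the five layers is (64, 48, 32, 16,
  8): narrow enough that a full training run stays tractable on one CPU
  core, while the late, high-resolution layers still shape a single-peak
  response; the schedule is configurable, and heatmap-variant parameter
  counts depend on it.

Supervision targets for the heatmap head are isotropic Gaussians rendered
on the head's output grid, normalized to peak value 1 at the grid point
nearest the keypoint. Decoding finds the global maximum (ties: smallest
row-major index), clamps negative responses to zero, and takes the
intensity-weighted mean position over the 13x13 window centered on the
maximum, clipped at borders, then scales grid to input-crop coordinates.
The weighted (not unweighted) mean is used because an unweighted window
mean would always return the window center and carry no information; the
weighted rule is an identity to <= 0.1 px for interior keypoints at
sigma = 3 and equivariant to horizontal flips up to floating-point
round-off (an exact half-pixel keypoint ties two grid maxima, and the
tie-break then anchors the window asymmetrically under the flip).

Dropout (rate 0.5) is applied in the head during training: before the
final linear layer (regression) or the final 1x1 convolution (heatmap).
In the heatmap head it is deliberately placed *after* the batch-normalized
upsampling stack — dropout ahead of batch normalization would collect
running statistics under dropout noise and then apply them to undropped
activations at inference, systematically shrinking the response map.

Pretrained ImageNet backbone initialization is supported by loading a
user-supplied checkpoint (`load_checkpoint`); `build_model` itself always
initializes randomly (Kaiming), so all tests and the acceptance run train
from scratch.

## Training

SGD with momentum 0.9 and weight decay 1e-4; mean-square error of the
prediction as the loss (normalized coordinates for the regression head,
per-pixel on response maps for the heatmap head); learning rate decayed by
a factor 0.1 after 10 epochs; at most 20 epochs with early stopping at
patience 4 ("did not decrease" = not strictly below the best value seen);
the best-validation weights are restored at the end, since that is the
model one evaluates. Dropout 0.5 as above. Batch size and learning rate
are tuned per model on validation data; batch size lies in [8, 12].

Side-view and frontal-view models are always trained separately — the
foot's appearance and the heel-keypoint definition both differ between
views — and the trainer refuses mixed-view datasets.

Training is bit-reproducible on a fixed machine under fixed seeds: batch
shuffling and dropout are the only stochastic elements and both derive
from explicit generators.

### Desk-scale optimization behavior

With the clinical corpus (193 k side images after augmentation), one epoch
is ~19,000 SGD steps; a desk-scale synthetic run (~800 crops) has ~100.
Under plain SGD with per-pixel-mean MSE — where background pixels outweigh
the Gaussian peak ~200:1 — a from-scratch network at this step count
converges to the near-constant background solution: the optimal linear
readout of uninformative random features is close to zero, and gradients
into the backbone are scaled by those near-zero readout weights, a mutual
deadlock. (Measured directly: a ridge readout of the random-initialized
MobileNetV2 feature stack predicts the heel no better than predicting the
mean position; a small encoder-decoder trained under the identical
protocol collapses the same way, so the effect is a property of the
optimization regime, not of a particular architecture.) The original
method breaks this deadlock with ImageNet-pretrained backbones — its
stated reason for transfer learning — and with two orders of magnitude
more optimization steps. The trainer here implements the protocol
faithfully and reports measured errors; desk-scale from-scratch runs
demonstrate the full mechanics (schedule, early stopping, restoration,
reproducibility) but do not reach clinical-grade localization, and the
measured held-out error reflects that honestly.

## Evaluation

The clinically relevant error is the distance between predicted and
labelled heel points *along one floor axis in world coordinates*: the
walking direction (floor x) for side views — the component that corrupts
step length — and the lateral direction (floor y) for frontal views, which
corrupts step width. Crop coordinates are shifted by the crop origin,
projected through the homography, and differenced.

Error summaries follow the box-plot convention: quartiles by linear
interpolation of order statistics (quartile k at rank k/4 x (n-1),
0-based), IQR = Q3 - Q1, data extremes, and the fraction of values beyond
1.5 x IQR from the quartiles as outliers. Statistics are reported to three
decimals. Step length and width are |Delta x| and |Delta y| between
successive (alternating-foot) heel contacts on the floor.

## Synthetic data

The clinical recordings contain sensitive personal data and are not
distributable, so every input kind is emulated with exact ground truth:

* **Foot crops.** A foot-like silhouette (randomized length, height,
  posterior/anterior curvature, leg lean, toe-up pitch of up to 5 degrees
  about the heel) over textured floor and background regions with
  randomized colors, blotch textures, shading, blur and pixel noise. The
  silhouette is constructed so its most posterior (side) / most lateral
  (frontal) floor-contact pixel is the declared heel keypoint, within 1 px
  (verified by scanning the rendered mask). The pitch rotation is applied
  about the heel and only toe-up, so it preserves that guarantee — a
  free-angle rotation would move the contact point off the closed-form
  label. Scenes render inside a 320x240 virtual frame with the crop
  window centered, leaving 80/60 px margins so the +-30 px augmentation
  translations never need padding.
* **Gait trajectories.** Heel floor positions follow stance plateaus with
  linear swing transitions; the foot that lands rests until the other foot
  lands, which then swings, arriving exactly on its planted strike frame.
  This makes the heel-to-heel distance strictly increase into every strike
  frame and strictly decrease after it, so its local maxima (in floor and,
  for the mild perspective of a plausible side camera, in image
  coordinates) sit exactly on the planted frames. Strike positions advance
  by the planted step length along floor x and alternate +-(step width)/2
  in floor y; image positions come from the inverse homography, with
  optional Gaussian pixel noise. Approximate ankle/toe keypoints are
  emitted alongside the heels so the centroid/cropping path can run.
* **Calibration scenes.** Jittered-grid floor points (never collinear)
  with exact projections, plus optional image noise.

What the generators do *not* emulate: real footwear/floor appearance
diversity, motion blur, occlusion by the contralateral foot, airborne-heel
trajectories during swing (heels slide on the floor plane between
strikes), camera distortion, and pose-estimator failure modes beyond
confidence-zero dropouts. Passing tests therefore demonstrate that the
pipeline's geometry, bookkeeping and optimization are correct and that the
networks can learn heel localization from images at desk scale — not that
clinical-grade accuracy (median ~0.5 cm) transfers to real recordings;
that depends on the clinical corpus.

## Numerical choices

* Float32 training; float64 for homography estimation and gradient checks.
* Batch statistics use a one-pass sum/sum-of-squares kernel; variance is
  clamped at zero; eps 1e-5; running-stat momentum 0.1 (unbiased variance
  in the running estimate).
* Heatmap decode anchors ties at the smallest row-major index; negative
  responses are clamped before weighting; an all-nonpositive map raises
  rather than guessing.
* Projection treats |w| < 1e-12 in homogeneous coordinates as a point at
  infinity and raises.
* Peak pruning keeps the earlier frame on exact height ties.
* Crop windows at frame borders are shifted, not padded.
* The engine's convolutions run as BLAS GEMMs over im2col patch matrices,
  with compiled kernels for the scatter-add inverse, depthwise 3x3
  convolutions and batch-norm reductions; gradients of every layer are
  verified against central finite differences in float64.

## Desk-scale problem sizes

Tests and the acceptance script use: 6-8 calibration points; 100-frame
gait scenarios with 3-7 strikes; ~1,000 rendered crops (800 train /
100 validation / 100 test, split by synthetic subject) for the from-scratch
training of the mobilenetv2-heatmap variant, 12 epochs at batch 8. These
sizes exercise every code path while keeping a full run in the tens of
minutes on one CPU core.

## Known limitations

* Training the deep keypoint networks from random initialization at
  desk-scale step counts does not produce usable localization under the
  prescribed optimization protocol (see "Desk-scale optimization
  behavior"); pretrained backbone weights, supplied as a checkpoint, are
  required for accuracy comparable to the published results.
* Heatmap-variant parameter counts depend on the chosen transposed-conv
  channel schedule and are not comparable to the published heatmap counts,
  whose exact head hyperparameters are not recoverable.
* The standard ResNeXt-50 (32x4d) yields 25.0 M parameters where the
  published table lists 29.0 M for the resnext50-regression variant; the
  exact variant behind that count is not recoverable either.
* Step parameters assume successive detected strikes alternate feet;
  pathological gait violating this needs per-foot event assignment first.
* The pose parser takes person 0; multi-person scenes need upstream
  tracking.
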