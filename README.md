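# gaitheel

Marker-less extraction of heel contact points — and from them step length
and step width — from ordinary video recordings of walking, such as Timed
Up and Go (TUG) tests filmed at 25 Hz from the side and the front. The
package is aimed at movement-analysis researchers who have whole-body pose
estimates (the 25-keypoint JSON dialect) for their videos and want metric
gait parameters from a single calibrated camera, without markers on the
participant.

## The method

The pipeline has two steps.

**Coarse step.** Pose-estimator keypoints, though too noisy for clinical
gait parameters on their own, are good enough to find gait, events and
feet. The heel strike is approximated by the frame at which the absolute
heel-to-heel image distance d(t) = ||p_L(t) − p_R(t)|| peaks: at landing,
the feet are maximally apart. At such a frame the foot is cropped to a
fixed 160x120 window centered on the centroid of the ankle, big-toe and
heel keypoints.

**Fine step.** A dedicated convnet predicts the *heel keypoint* in the
crop: the most posterior (side view) or most lateral (frontal view) point
of the heel in contact with the floor. Six variants combine three
backbones (VGG19, ResNeXt-50 32x4d, MobileNetV2) with two heads — a
regression head (backbone's 1000-way output + a fully connected 1000 -> 2
layer emitting normalized coordinates) and a heatmap head (backbone
feature layers + five stride-2 transposed convolutions + a 1x1
convolution; the keypoint is decoded as the intensity-weighted mean over
the 13x13 neighborhood of the response maximum). Training uses SGD
(momentum 0.9, weight decay 1e-4), MSE loss, learning rate decayed 0.1x
after 10 epochs, at most 20 epochs with early stopping at patience 4, and
dropout 0.5 in the head.

**Calibration.** Because the heel keypoint lies on the floor plane by
definition, a planar homography H (estimated from >= 4 marked floor points
with the normalized DLT) maps it to metric floor coordinates
(x, y) in cm, with x along the walking axis. Step length and width are
|Δx| and |Δy| between successive alternating-foot contacts, and model
accuracy is judged by the error along the step-relevant floor axis.

The clinical recordings behind the method are not distributable, so the
`synth` module generates every input kind with exact ground truth:
textured foot crops with a known heel point, gait-like keypoint
trajectories with planted heel strikes, and calibration scenes from a
known homography. See `docs/methods.md` for the model, assumptions, and
what the synthetic fixtures do and do not demonstrate.

## A worked example

`examples/02_detect_heel_strikes.py` synthesizes a 4-second walk with heel
strikes planted at frames 20, 45 and 70 (step length 60 cm, step width
10 cm), detects the strikes, and projects the strike-frame heel positions
onto the floor:

```
planted heel strikes:  [20, 45, 70]
detected heel strikes: [20, 45, 70]
step lengths (cm): [60. 60.]
step widths  (cm): [10. 10.]
```

The detected frames coincide with the planted ones, and the floor
projection returns the planted step geometry exactly — on noiseless input
the coarse step and the calibration are loss-free, so any error in a real
analysis comes from keypoint prediction and labelling, which is what the
fine step is evaluated on. The other examples cover floor calibration
(`01`), heatmap rendering/decoding (`03`), error statistics (`04`), and a
small training run (`05`).

A thin CLI mirrors the library: `gaitheel synth-feet | synth-gait |
synth-calib | calibrate | detect-events | train | predict | evaluate`
(see `gaitheel --help`).

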