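"""Floor-axis errors and box-plot summary statistics.

Projects predicted and labelled heel keypoints onto the floor and measures
the error along the walking axis (the component that corrupts step length),
then summarizes a small error sample with the box-plot convention: median,
quartiles, IQR and the fraction of outliers beyond 1.5 x IQR.
"""

from gaitheel import floor_axis_error, summarize_errors
from gaitheel.geometry import ImagePoint
from gaitheel.synth import example_homography

camera = example_homography()
pred = ImagePoint(83.0, 96.0)
label = ImagePoint(80.0, 96.0)
err = floor_axis_error(pred, label, crop_origin=ImagePoint(500, 400),
                       h=camera, view="side")
print(f"3 px image offset at this floor position -> {err:.3f} cm along the "
      "walking axis")

errors_cm = [1, 2, 3, 4, 100]
s = summarize_errors(errors_cm)
print(f"\nerrors {errors_cm} summarize to:")
print(f"  median {s.median:.3f}  Q1 {s.q1:.3f}  Q3 {s.q3:.3f}  "
      f"IQR {s.iqr:.3f}")
print(f"  min {s.min:.3f}  max {s.max:.3f}  outlier fraction "
      f"{s.outlier_fraction:.3f}")
print("-> the value 100 lies above Q3 + 1.5 x IQR = 7, so 1 of 5 points")
print("   (20%) is flagged as an outlier.")
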