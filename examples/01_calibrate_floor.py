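"""Floor calibration: estimate the image->floor homography from marked points.

Builds a synthetic calibration scene from a known side-view camera (six
floor marks at known cm positions plus their image projections), then
re-estimates the homography with the normalized DLT and reports how well
the generating matrix and the floor positions are recovered.
"""

import numpy as np

from gaitheel import (
    estimate_homography,
    project_to_floor,
    synth_calibration_scene,
)
from gaitheel.synth import example_homography

true_h = example_homography()
pairs = synth_calibration_scene(true_h, n_points=6, noise_sd=0.0, rng_seed=42)

est = estimate_homography(pairs)
matrix_err = np.abs(est.h - true_h.h).max()

print("estimated homography (image -> floor, cm):")
print(np.array_str(est.h, precision=6, suppress_small=True))
print(f"max |entry difference| to the generating matrix: {matrix_err:.2e}")

worst = 0.0
for ip, fp in pairs:
    proj = project_to_floor(est, ip)
    worst = max(worst, float(np.hypot(proj.x - fp.x, proj.y - fp.y)))
print(f"worst floor-point reprojection error: {worst:.2e} cm")
print("-> noiseless marks are recovered to numerical precision; the same")
print("   call handles noisy, hand-clicked marks in real calibrations.")
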