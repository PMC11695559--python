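"""Target heatmaps and sub-pixel decoding.

Renders the Gaussian supervision target for a heel keypoint at a sub-pixel
position and decodes it back with the 13x13 weighted-mean rule used on
network outputs, demonstrating the sub-0.1 px round trip and the exact
horizontal-flip equivariance of the decoder.
"""

import numpy as np

from gaitheel import decode_heatmap, render_target_heatmap
from gaitheel.geometry import ImagePoint
from gaitheel.models import Heatmap

target = ImagePoint(45.25, 30.75)
hm = render_target_heatmap(target, shape=(120, 160), sigma=3.0)
decoded = decode_heatmap(hm)

print(f"keypoint rendered at   ({target.x}, {target.y})")
print(f"decoded from heatmap   ({decoded.x:.4f}, {decoded.y:.4f})")
print(f"round-trip error       {np.hypot(decoded.x - target.x, decoded.y - target.y):.4f} px")

flipped = Heatmap(np.ascontiguousarray(hm.values[:, ::-1]))
q = decode_heatmap(flipped)
print(f"decoded after flip     ({q.x:.4f}, {q.y:.4f}); "
      f"mirror of original x = {159 - decoded.x:.4f}")
print("-> the decoder is an identity (<= 0.1 px) for interior keypoints and")
print("   mirrors exactly (to round-off) under horizontal flips.")
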