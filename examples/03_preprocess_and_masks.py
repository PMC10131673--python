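"""Color normalization and attention-mask construction.

ACE removes global lighting shifts (it sees only pixel differences);
lesion boxes become soft heatmap targets on the encoder's coarse grid.
"""

import numpy as np

from pasivision import ace_normalize, boxes_to_heatmap
from pasivision.synth import LesionParams, generate_region_images

# Render the same skin under two lighting conditions.
params = LesionParams(0.3, 0.7, 0.4, 0.5, lighting_jitter=0.15)
(img_a, boxes), (img_b, _) = generate_region_images(params, 2, (64, 80), seed=9)
print("raw mean intensity per view:", img_a.mean().round(1), img_b.mean().round(1))

norm_a, norm_b = ace_normalize(img_a), ace_normalize(img_b)
print("after ACE:", norm_a.mean().round(1), norm_b.mean().round(1))
# ACE pulls both views to a common photometric frame (means nearly equal).

heat = boxes_to_heatmap(boxes, (64, 80), (8, 10))
print("heatmap grid 8x10; coverage fraction:", round(float(heat.values.mean()), 3))
print(np.array2string(heat.values, precision=2, suppress_small=True))
# Each cell holds the fraction of its receptive area covered by lesion
# boxes — the supervision target for the attention branch.
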