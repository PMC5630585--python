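"""Refine a poor outline with helper seeds, as an examiner would.

Builds a large, subtle lesion whose raw cut wanders (on big lesions the
radial sampling is coarse relative to the speckle grain, so spurious gray
matches inside the lesion compete with the boundary), segments it from the
centroid seed, then adds helper seeds on the true
boundary at the worst-error angles and re-solves after each. The printed
DSC trace shows how each helper pulls the contour onto the boundary.
"""

import numpy as np

from uscut import PhantomSpec, dice, generate_phantom, segment
from uscut.evaluate import auto_helpers
from uscut.image_io import PointPx
from uscut.interactive_segmentation import resegment

case = generate_phantom(PhantomSpec(image_size=220, base_radius=60.0,
                                    boundary_harmonics=((0.08, 3, 0.7),),
                                    lesion_gain=0.2, rng_seed=1))
ys, xs = np.nonzero(case.truth_mask.pixels)
seed = PointPx(float(xs.mean()), float(ys.mean()))

result = segment(case.image, seed)
print(f"helpers=0  DSC={dice(result.mask, case.truth_mask):.1f} %")
used: set[int] = set()
for n in range(1, 5):
    proposal = auto_helpers(case, seed, result, used)
    if proposal is None:
        break
    helper, ray = proposal
    used.add(ray)
    result = resegment(case.image, result, added_helpers=[helper])
    print(f"helpers={n}  DSC={dice(result.mask, case.truth_mask):.1f} %"
          f"  (helper on ray {ray})")
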