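"""Directional pipeline vs omni-directional baseline on hard phantoms.

The hard suite contains curved vessels down to 1 px wide at 30% contrast
with a central light reflex — the regime where an omni-directional
winning-line search lets high-contrast structure drown out faint vessels.
The directional pipeline scans each orientation sub-band separately, so
faint aligned vessels are not out-competed.  Prints the per-image and
mean sensitivities of both.
"""

import numpy as np

from dirvessel import PipelineConfig, confusion, metrics, segment, segment_baseline
from dirvessel.phantom import phantom_suite

config = PipelineConfig()
rows = []
for i, (rgb, truth, fov) in enumerate(phantom_suite("hard", n=4)):
    sn_dir = metrics(confusion(segment(rgb, fov, config), truth, fov)).sn
    sn_omni = metrics(confusion(segment_baseline(rgb, fov, config), truth, fov)).sn
    rows.append((sn_dir, sn_omni))
    print(f"hard image {i}: directional Sn={sn_dir:.3f}  omni Sn={sn_omni:.3f}")
d, o = np.mean([r[0] for r in rows]), np.mean([r[1] for r in rows])
print(f"mean: directional {d:.3f} vs omni {o:.3f} "
      f"(gain {d - o:+.3f} — faint vessels survive the directional scan)")
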