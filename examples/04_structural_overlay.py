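"""Overlay a reconstruction on a structural image.

Uses the thorax mask as a synthetic stand-in for a co-registered structural
(CT-like) slice, reconstructs pattern (c), and writes an alpha-blended PNG:
strong conductivity decrease appears white/light blue over the anatomy.
"""

from pathlib import Path

import numpy as np

from eitdct import make_ventilation_pattern
from eitdct.pipeline import (StudyConfig, build_suite, reconstruct_all,
                             render_overlay, simulate_pattern)

suite = build_suite(StudyConfig())
pattern = make_ventilation_pattern(suite.phantom, "c")
y = simulate_pattern(suite, pattern.ventilated_mask)
H = reconstruct_all(suite, y)["dct"]

# synthetic structural raster: brighter thorax, darker lungs (CT-like contrast)
structural = 0.6 * suite.phantom.thorax_mask().astype(float)
structural[suite.phantom.lung_mask.astype(bool)] = 0.25

out = Path("scratch")
out.mkdir(exist_ok=True)
render_overlay(H, structural, out / "overlay_pattern_c.png")
print(f"overlay written to {out / 'overlay_pattern_c.png'}")
print(f"reconstruction range: [{H.min():.3f}, {H.max():.3f}] "
      f"(negative = conductivity decrease = ventilated tissue)")
print(f"pixels outside lungs untouched: max|H| there = "
      f"{np.max(np.abs(H[suite.phantom.lung_mask == 0])):.2g}")
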