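"""Local gyrification on a synthetic folded cortex.

Builds a folded sphere (ripples confined to a patch), computes the outer
hull by morphological closing, and prints the local gyrification index
(lGI) inside and outside the patch. lGI ~ 1 on smooth cortex and rises
where folding buries surface area.
"""

import numpy as np

from gyriconn import FoldSpec, compute_lgi, compute_outer_hull, generate_folded_surface

spec = FoldSpec(fold_amplitude=5.0, fold_frequency=3.0)
pial, white = generate_folded_surface(spec, seed=0)
hull = compute_outer_hull(pial, closing_diameter=15.0, pitch=1.0)
lgi = compute_lgi(pial, hull, radius=25.0)

u = pial.vertices / np.linalg.norm(pial.vertices, axis=1, keepdims=True)
theta = np.arccos(np.clip(u @ np.array([1.0, 0.0, 0.0]), -1, 1))

print(f"pial area  {pial.area():8.0f} mm^2   hull area {hull.area():8.0f} mm^2")
print(f"lGI at patch centre : {lgi.values[theta < 0.1].mean():.3f}")
print(f"lGI far from patch  : {lgi.values[theta > 1.2].mean():.3f}")
print("Folding buries cortex: the patch ratio exceeds 1, the smooth far")
print("field stays at 1 (the hull coincides with the pial surface there).")
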