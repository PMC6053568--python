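"""Build the fractal habitat array and inspect its multi-scale structure.

The array nests patches in triangles of triangles: 3**4 = 81 patches with
aggregation scales 1, 3, 9, 27 and 81.  Spacings are the per-level
centroid-to-centroid distances in metres.
"""

import numpy as np

from metapred import build_fractal_layout, scale_partition

layout = build_fractal_layout(levels=4)
print(f"patches: {layout.n_patches}, scales: {layout.scales}")
print(f"spacings (m): {layout.spacings}")
print(f"array diameter: {layout.dist.max():.1f} m; "
      f"nearest-neighbour distance: {layout.dist[layout.dist > 0].min():.2f} m")

for scale in (3, 9, 27):
    part = scale_partition(layout, scale)
    d = layout.dist
    same = part[:, None] == part[None, :]
    off = ~np.eye(81, dtype=bool)
    print(f"scale {scale:2d}: {81 // scale:2d} groups; "
          f"max within-group distance {d[same & off].max():5.2f} m")

# Each group of the hierarchy is a contiguous block of patch indices, so the
# level-l group of patch i is simply i // 3**l.
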