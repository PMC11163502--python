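"""Center-weighted pooling: window counts, layout, and a worked pooling.

The operator halves a nodule-centred axis with small max-windows in the
middle (detail preserved where the target sits) and wide windows at the
edges.  Window counts per size solve a small linear system with the
closed form (Q/8, Q/4, Q/8).
"""

import numpy as np

from nodseg.pooling import build_partition, central_pool_1d, central_pool_2d, solve_kernel_counts

for q in (64, 8):
    n1, n2, n3 = solve_kernel_counts(q)
    part = build_partition(q)
    print(f"Q={q}: {n1} windows of size 1, {n2} of size 2, {n3} of size 3")
    if q == 8:
        print("  layout:", list(part.layout))

vals = np.array([5, 1, 4, 2, 8, 3, 7, 6], float)
print("pooling", vals.tolist(), "->", central_pool_1d(vals, build_partition(8)).tolist())
print("   (max over windows [0:3], [3:5], [5:6], [6:8])")

plane = np.zeros((8, 8))
plane[4, 4] = 9.0
print("8x8 plane with one hot voxel pools to:\n", central_pool_2d(plane))
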