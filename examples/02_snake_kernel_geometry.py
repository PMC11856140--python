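"""Visualize the geometry of the dynamic snake convolution kernel.

The 3x3x3 kernel is linearized into a 9-tap polyline per axis; each step's
lateral offsets accumulate, so the kernel bends to follow elongated
structures.  With offsets saturated at the unit bound, the three
axis-variants together reach a 9 x 9 x 9 cube — the operator's selectable
receptive field.
"""

import numpy as np

from snakereg import SnakeKernelSpec, receptive_extent, snake_positions
from snakereg.snake import enumerate_saturated_positions

spec = SnakeKernelSpec()  # 9 taps, |offset| <= 1 per step
print(f"taps per axis-variant:  {spec.points_per_kernel}")
print(f"extent (along, lat, lat): {receptive_extent(spec)}")

# a gently bending x-snake
off = np.zeros((2, 4, 2))
off[1, :, 0] = [0.5, 0.5, -0.25, 0.1]  # plus side bends up in d, then back
pos = snake_positions((0, 0, 0), off, "x", spec)
print("\nx-snake sampling polyline (d, h, w):")
for p in pos:
    print(f"  ({p[0]:+.2f}, {p[1]:+.2f}, {p[2]:+.2f})")

sat = enumerate_saturated_positions(spec)
cube = sat.max(axis=0) - sat.min(axis=0) + 1
print(f"\nbounding cube of all saturated positions: "
      f"{cube[0]:.0f} x {cube[1]:.0f} x {cube[2]:.0f}")

small = SnakeKernelSpec(points_per_kernel=9, max_step=0.5)
print(f"with half-voxel steps the lateral reach shrinks: {receptive_extent(small)}")
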