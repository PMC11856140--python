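"""Generate a brain-like phantom pair with a known deformation and verify it.

The moving image is a nested-ellipsoid phantom; the fixed image is the same
phantom resampled through a smooth random displacement field, so the true
correspondence is known exactly.  The printed numbers show that (a) the
deformation really moved the anatomy (label overlap < 1 before registration)
and (b) warping with the true field restores perfect overlap with zero
folding — the generator's own acceptance property.
"""

import numpy as np

from snakereg import (FieldSpec, PhantomSpec, dice, jacobian_determinant,
                      make_pair, pct_nondiffeomorphic, warp_volume)

case = make_pair(PhantomSpec(shape=(32, 32, 32)), FieldSpec(amplitude=2.0), seed=7)

_, dice_before = dice(case.moving_labels, case.fixed_labels)
warped_labels = warp_volume(case.moving_labels, case.gt_field, mode="nearest")
_, dice_after = dice(warped_labels, case.fixed_labels)
jac = jacobian_determinant(case.gt_field)

print(f"labels:                  {sorted(int(v) for v in np.unique(case.moving_labels.labels))}")
print(f"max displacement:        {np.abs(case.gt_field.vectors).max():.3f} voxels")
print(f"Dice before alignment:   {dice_before:.4f}   (deformation moved the structures)")
print(f"Dice with the true field:{dice_after:.4f}   (exact by construction)")
print(f"min Jacobian det:        {jac.det.min():.4f}   (> 0: fold-free)")
print(f"% voxels with det <= 0:  {100 * pct_nondiffeomorphic(jac):.4f}")
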