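"""The evaluation metrics and training costs on a worked micro-example.

SDC = 2tp/(2tp+fp+fn); the TP-weighted variant scales tp by w so surface
errors (fp/fn) weigh relatively more; the combined cost adds the Hausdorff
distance normalized by 0.33x (x = ROI diagonal, the maximum possible HD).
"""

import numpy as np

from oarseg.core import default_roi_spec
from oarseg.losses import LossSpec, combined_loss
from oarseg.metrics import contour_complexity, hausdorff_3d, sdc, weighted_sdc

# masks realizing tp=3, fp=1, fn=2
pred = np.zeros((6, 1, 1), dtype=np.uint8)
ref = np.zeros((6, 1, 1), dtype=np.uint8)
pred[:4] = 1
ref[:3] = 1
ref[4:] = 1
print(f"SDC        = {sdc(pred, ref):.4f}   (2*3 / (2*3+1+2) = 0.6667)")
print(f"SDC(0.5)   = {weighted_sdc(pred, ref, 0.5):.4f}   (3 / 6)")
print(f"SDC(0.05)  = {weighted_sdc(pred, ref, 0.05):.4f}   (0.3 / 3.3)")

spec = default_roi_spec("SMG")  # 64 x 64 x 32 ROI
print(f"SMG ROI diagonal x = {spec.roi_diagonal:.0f} voxels, "
      f"HD normalizer 0.33x = {0.33 * spec.roi_diagonal:.2f}")

a = np.zeros((8, 8, 8), dtype=np.uint8)
b = np.zeros_like(a)
a[1, 1, 1] = 1
b[4, 5, 1] = 1
print(f"HD between voxels (1,1,1) and (4,5,1) = {hausdorff_3d(a, b):.1f} (3-4-5 triangle)")

ls = LossSpec(kind="sdc_plus_hd", roi_diagonal=spec.roi_diagonal)
perfect = ref.astype(float)
print(f"combined cost of a perfect prediction = {combined_loss(perfect, ref, ls):.4f}")

x, y = np.ogrid[0:64, 0:64]
disk = (((x - 32) ** 2 + (y - 32) ** 2) < 20 ** 2).astype(np.uint8)[:, :, None]
print(f"contour complexity of a disk r=20: {contour_complexity(disk):.3f} "
      f"(continuum limit 2/r = {2 / 20:.3f}; lower = smoother)")
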