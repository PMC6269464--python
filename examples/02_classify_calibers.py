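"""Classify vessel voxels by caliber from minimal projected cross-sections.

Every vessel voxel gets the area of the smallest 2D connected section
through it among the three orthogonal slicing planes; areas are binned into
seven descending classes (74.6 µm² … 0).  Voxels whose sections exceed
74.6 µm² are "over-caliber" and excluded from the analysis.
"""

import numpy as np

import angioarch as aa

# a crafted stack: one fat tube (class 1), one medium (class 4), one
# capillary-like single-voxel line (class 7)
vox = np.zeros((40, 40, 40), dtype=bool)
vox[:, 4:16, 4:16] = True     # 12×12 = 144-voxel section → 42.0 µm², class 1
vox[:, 24:29, 24:29] = True   # 5×5 = 25-voxel section → 7.29 µm², class 4
vox[:, 34, 34] = True         # 1-voxel section → 0.29 µm², class 7
stack = aa.BinaryStack(aa.GridMeta(0.54, vox.shape), vox)

prepared = aa.prepare_stack(stack)           # fill hollow lumina (none here)
classified = aa.classify_voxels(prepared)

scheme = classified.scheme
print("class boundaries (µm²):", scheme.boundaries_um2)
for k, count in classified.class_counts().items():
    if count:
        name = "OVER (> 74.6 µm², excluded)" if k == aa.OVER_LABEL else f"class {k}"
        print(f"  {name}: {count} voxels")

# The three tubes land in classes 1, 4 and 7: the caliber proxy is the
# minimal projected section area, so the 144-voxel transverse section of
# the fat tube (144 × 0.2916 ≈ 42 µm²) falls in the 74.6–37.3 µm² class.
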