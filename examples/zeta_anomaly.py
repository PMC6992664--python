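"""The zeta anomaly score, from a hand-checkable example to a voxel map.

Zeta is the mean distance from a sample to its k nearest reference
neighbours minus the mean pairwise distance among those neighbours: a point
inside the reference cloud scores near zero, an outlier scores high.
"""

import numpy as np

from ctseg import BinaryMask, PhantomConfig, ZetaConfig, make_phantom, zeta_map, zeta_score
from ctseg.phantom import LesionSpec
from ctseg.zeta import ReferenceCohort

# 1-D references {0, 1, 2, 10}, test point 5, k=2: the nearest neighbours are
# {2, 1}; mean distance to the test point is (3+4)/2 = 3.5 and the neighbours
# are 1 apart, so zeta = 3.5 - 1 = 2.5.
score = zeta_score(np.array([5.0]), np.array([0.0, 1.0, 2.0, 10.0]), k=2)
print(f"hand example zeta          : {score:.2f}")

# Voxel-wise: a lesioned phantom against a lesion-free cohort.
shape, spacing = (24, 24, 24), (4.0, 4.0, 4.0)
lesion = LesionSpec(center_mm=(-14.0, 4.0, 2.0), radii_mm=(8.0, 8.0, 8.0))
vol, truth = make_phantom(PhantomConfig(shape=shape, spacing=spacing, lesion_specs=(lesion,), seed=5))
cohort = ReferenceCohort(
    [make_phantom(PhantomConfig(shape=shape, spacing=spacing, seed=s, asymmetry_jitter_mm=1.0))[0]
     for s in range(3, 9)]
)
domain = BinaryMask(vol.data < 100, spacing)
zmap = zeta_map(vol, cohort, domain, ZetaConfig(k=3))

inside = zmap.data[truth.lesion_mask.data].mean()
outside = zmap.data[domain.data & ~truth.lesion_mask.data].mean()
print(f"mean zeta inside lesion    : {inside:.1f}")
print(f"mean zeta outside lesion   : {outside:.1f}")
# The lesioned tissue is far from every reference patch at that location, so
# its zeta is much higher than the background level set by noise and jitter.
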