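"""Voxel-wise Mann-Whitney maps: exactness and calibration.

Shows the exact small-sample test against hand-computable cases, then
simulates null cohorts (14 vs 14 subjects at 1000 locations) and checks
that the fraction of significant voxels matches the nominal alpha = 0.05.
"""

import numpy as np

from flow4d import mann_whitney_u, pvalue_map
from flow4d.atlas import CohortMap, SharedGeometry
from flow4d.core import AortaMask
from flow4d.segment import extract_wall

u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
print(f"x=(1,2,3) vs y=(4,5,6): U={u:.0f}, two-sided exact p={p:.3f}  (2/C(6,3) = 0.100)")

mask = AortaMask(np.ones((10, 10, 10), bool), (2.0, 2.0, 2.0))
shared = SharedGeometry(mask=mask, wall=extract_wall(mask), inclusion_fraction=1.0,
                        reference_index=0, rigid_transforms=[])

fractions = []
for seed in range(10):
    rng = np.random.default_rng(seed)
    a = CohortMap(rng.normal(size=(14, 1000)), shared, "voxel")
    b = CohortMap(rng.normal(size=(14, 1000)), shared, "voxel")
    pm = pvalue_map(a, b, alpha=0.05, min_n=7)
    fractions.append(pm.significant.sum() / pm.testable.sum())
print(f"null significant-voxel fraction: {100 * np.mean(fractions):.2f}%  (nominal 5%)")
print(
    "Under the null the per-voxel test flags ~5% of locations, i.e. the map"
    " is calibrated; apparent 'significant volume' of that size is noise."
)
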