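"""Two-cohort comparison on synthetic subjects.

Generates two small cohorts whose only systematic difference is jet
centrality — an eccentric jet (displaced 4 mm, emulating flow downstream of
a stented valve prosthesis) versus a central jet (stentless-like) — runs
every subject through preprocessing and haemodynamic quantification, builds
the shared geometry, and prints the conventional group table plus the
significance fractions of the per-voxel p-value maps.
"""

import logging

from flow4d import PhantomConfig, generate_cohorts
from flow4d.pipeline import PipelineConfig, run_cohort_comparison

logging.basicConfig(level=logging.WARNING)

base = PhantomConfig(
    grid_shape=(36, 42, 28), tube_radius=8.0, tube_length=48.0, n_frames=6,
    v_max=2.2, profile="eccentric_jet", jet_offset=0.0,
    venc=(2.5, 2.5, 2.5), noise_sigma=0.05,
)
group_a, group_b = generate_cohorts(4, base, effect=(4.0, 0.0), seed=3)
report = run_cohort_comparison(group_a + group_b, PipelineConfig(seed=0, min_n=3))

print("Group table (A = eccentric jet, B = central jet):")
print(report.group_table.round(3).to_string())
print()
print("Significance fractions (percent of analysed volume / wall surface):")
print(report.fractions.round(1).to_string())
print()
print(
    "The averaged metrics barely separate the groups, while the per-voxel"
    " maps localize where the central-jet cohort is faster (core) and where"
    " the eccentric-jet cohort dominates (outer lumen, wall shear stress)."
)
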