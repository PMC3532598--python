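"""Simulate a small synthetic group and inspect its structure.

Each subject gets S sessions of n trials; every trial is an anticipation
cue (4-8 s) followed by a 1 s near-threshold stimulus the subject perceives
as painful or not.  A weak class signal is planted in a subset of atlas
regions; everything else is AR(1) noise plus slow drift.
"""

import numpy as np

import painscale as ps

group = ps.generate_group(
    n_subjects=3,
    S=2,
    trials_per_session=10,
    grid_shape=(8, 8, 8),
    n_regions=6,
    n_control=2,
    master_seed=7,
    effect_size_mean=1.0,
    effect_size_sd_between_subjects=0.3,
)

atlas = group[0].atlas
print(f"{len(group)} subjects, grid {atlas.grid_shape}, "
      f"{len(atlas.region_names)} regions ({len(atlas.control_regions)} controls)")
for ds in group:
    n_pain = sum(e.label == "pain" for e in ds.events)
    print(
        f"subject {ds.subject_id}: volumes {ds.volumes.shape}, "
        f"{len(ds.events)} trials ({n_pain} perceived painful), "
        f"per-subject effect size {ds.effect_size:.2f}"
    )
informative = ds.truth.informative_voxel_mask.sum()
print(f"planted signal in {informative} voxels "
      f"({informative / atlas.brain_mask().sum():.0%} of in-brain voxels)")
# The effect size is the amplitude difference between painful and
# non-painful trials in informative voxels; it varies across subjects,
# which is the random-effects structure the group test assumes.
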