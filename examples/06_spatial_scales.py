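"""Compare decoding accuracy across spatial scales.

Ranks atlas regions by the significance of their group accuracies, then
decodes from single regions, cumulative unions of the top regions, the
full pain-related set, the whole brain, and t-contrast-selected voxel sets
of tripling size -- the question being at which spatial scale the percept
is best read out.
"""

import painscale as ps
from painscale.multiscale import (
    cumulative_roi_combinations,
    roi_group_results,
    roi_rank_order,
    scale_curve,
)

group = ps.generate_group(
    n_subjects=4, S=2, trials_per_session=16,
    grid_shape=(8, 8, 8), n_regions=6, n_control=2,
    master_seed=21, effect_size_mean=2.5, effect_size_sd_between_subjects=0.5,
    n_informative_regions=2,
)
atlas = group[0].atlas
betas = [ps.beta_series_for_dataset(d) for d in group]
config = ps.DecodingConfig(C_grid=(1.0,), phase="stimulation")

results = roi_group_results(betas, atlas, config, N_perm=49, perm_seed=1)
ranking = roi_rank_order(results, alpha=0.05)
print("regions by significance (p, then accuracy):")
print(ranking.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

specs = cumulative_roi_combinations(ranking, ks=[1, 2, 3], atlas=atlas)
specs += [ps.FeatureSpec.top_voxels(k) for k in (1, 3, 9)]
curve = scale_curve(betas, atlas, config, specs=specs, N_perm=49, perm_seed=2)
print("\naccuracy by feature space:")
print(curve.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

p = ps.compare_scales(curve, curve.table["spec"].iloc[0], "whole_brain", N=500, seed=3)
print(f"\npaired sign-flip test, best single region vs whole brain: p = {p:.3f}")
# Accuracy typically rises from single voxels/regions to unions of the most
# predictive regions; the paired test asks whether two scales differ.
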