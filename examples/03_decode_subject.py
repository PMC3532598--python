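"""Decode perceived pain for a single subject.

Leave-one-session-out outer cross-validation; within each training fold the
voxel standardization, per-trial l2 scaling and the nested leave-one-trial-
out choice of the SVM regularization parameter C all see training trials
only.  Decoding runs separately per threat condition; the subject's score
is the mean of the two condition accuracies.
"""

import painscale as ps

atlas = ps.generate_atlas((8, 8, 8), n_regions=6, n_control=2, rng_seed=1)
signal = ps.make_signal_spec(atlas, n_informative_regions=2, rng_seed=2,
                             effect_size_mean=2.0, effect_size_sd_between_subjects=0.0)
events = ps.generate_events(S=2, n=14, rng_seed=3)
subject = ps.simulate_subject(events, atlas, signal, rng_seed=4)
beta = ps.beta_series_for_dataset(subject)

config = ps.DecodingConfig(C_grid=(0.1, 1.0, 10.0), phase="stimulation")
acc, folds = ps.decode_subject(beta, config, atlas=atlas)

print(f"high-threat accuracy: {acc.accuracy_high_threat:.2f} ({acc.n_trials_high} trials)")
print(f"low-threat accuracy:  {acc.accuracy_low_threat:.2f} ({acc.n_trials_low} trials)")
print(f"subject mean accuracy: {acc.mean_accuracy:.2f}  (0.5 = chance)")
for f in folds:
    print(f"  fold threat={f.threat} test-session={f.test_session}: "
          f"chosen C={f.chosen_C}, fold accuracy {f.accuracy:.2f}")
# The chosen C can differ between folds and conditions because each
# training fold reselects it with inner leave-one-trial-out validation.
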