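# painscale

Multivariate decoding of near-threshold pain perception from (synthetic)
fMRI, across spatial scales.

## The problem

When a laser stimulus is calibrated to an individual's pain threshold, the
*same* physical stimulus is sometimes felt as painful and sometimes not.
Whether the percept can be read out from distributed brain activity — and at
what spatial scale (single voxels, single anatomical regions, combinations
of regions, or the whole brain) the readout is best — is a question for
multivariate pattern analysis (MVPA).  This package implements the full
analysis workflow for that question as a tested, reusable library:

1. **Synthetic data** (`painscale.synthdata`): multi-subject BOLD
   simulation with the design the analysis assumes — S sessions × n trials
   per subject (default 4 × 30), anticipation periods of 4–8 s, 1 s
   stimuli, TR 3 s, a crossed two-level threat factor balanced within
   sessions, an atlas of 26 pain-related regions plus 2 auditory controls,
   weak distributed class signal confined to a subset of regions, AR(1)
   noise, low-frequency drift, and between-subject effect-size variability.
   Ground truth is retained for recovery tests.
2. **Trial-wise GLM** (`painscale.glm`): one boxcar regressor per trial and
   phase (anticipation/stimulation), convolved with the canonical
   double-gamma HRF; discrete-cosine high-pass filtering (cut-off 128 s)
   and pooled AR(1) whitening applied identically to data and design; the
   per-trial parameter estimates (beta series) are the decoder's input.
3. **Features** (`painscale.features`): per-voxel standardization (mean 0,
   sd 1, fit on training rows), per-trial l2 scaling to unit norm, ROI
   masking, and two-sample-t voxel ranking with 3^k selection schedules.
4. **Decoding** (`painscale.decoding`): linear soft-margin SVM,
   leave-one-session-out outer cross-validation, nested leave-one-trial-out
   selection of the regularization parameter C, condition-split analyses
   per threat level averaged into a subject accuracy, and group
   aggregation.
5. **Permutation inference** (`painscale.perminfer`): within-session label
   shuffles; p = (#null ≥ observed)/N with a 1/N floor; classifier
   weight-map inference via t_v = (w_v − μ̂_v)/σ̂_v against Student's
   t(N−1) with Bonferroni (or random-field-theory) family-wise error
   control; a Lilliefors audit of the Gaussian null summary; paired
   sign-flip tests between analyses.
6. **Spatial scales** (`painscale.multiscale`): regions ranked by the
   *significance* of their group accuracies, cumulative unions of the top
   regions, the "pain matrix" (all non-control regions), whole brain, and
   the tripling voxel-count curve — all on a common voxel-count axis.

A thin `painscale` command-line interface (`simulate`, `glm`, `decode`,
`weightmap`, `scales`, `report`, `run-all`) wraps the library for
end-to-end runs; `examples/` contains one short narrative script per
capability.

## A worked example

`examples/04_group_inference.py` simulates 6 subjects (2 sessions × 10
trials, weak planted signal), fits the trial-wise GLM, decodes perceived
pain from whole-brain activity, and runs the group permutation test:

```
per-subject mean accuracies: 0.90 1.00 0.95 0.65 0.90 0.95
group mean accuracy: 0.892 +/- 0.051 (SEM)
permutation p-value: 0.010  (N=99 within-session shuffles)
permutations needed for p<0.05 after Bonferroni over 26 regions: N >= 520
```

Each subject's accuracy is the mean of the high-threat and low-threat
analyses, pooled over left-out sessions; the p-value is the rank of the
observed group mean within 99 group means recomputed after shuffling
labels within each session × threat cell.  Here the planted effect is
strong enough that the observed mean exceeds all 99 permuted means, giving
the smallest attainable p (1/99 ≈ 0.01).  `examples/06_spatial_scales.py`
prints the scale comparison (single regions → unions → whole brain, and
the 3^k voxel curve) for the same kind of group.

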