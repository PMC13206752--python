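# Methods

This note records the models, defaults, and numerical choices behind
`marsa`, and what the synthetic-data experiments do and do not establish.

## Multiple-arrangement estimation

**Model.** An arrangement trial communicates the dissimilarities among the
displayed items only up to a positive scale: participants use whatever
spread the arena affords.  Each trial's pairwise Euclidean distances are
therefore divided by their root-mean-square before entering the estimate.
A trial's evidence about a pair is taken to be the squared scaled distance,
*w* = *d*²: a pair placed far apart is measured with better relative
precision than a pair whose items nearly touch, where pixel-scale placement
error dominates.  The running estimate of each pair is the evidence-weighted
mean of all its scaled measurements, updated incrementally per trial.

**Adaptive subsets.** After the first full-set trial, subsequent trials
show the items whose pairs have the weakest accumulated evidence: the
subset is grown greedily from the globally weakest pair, each step adding
the item that maximizes the summed evidence deficit
(threshold − evidence, floored at zero) over newly covered pairs, with ties
broken toward the lowest item index so selection is deterministic.  Subset
size defaults to 8 items; sessions terminate when every pair's evidence
reaches the threshold (default 0.5; per-trial pair evidence averages 1 for
a unit-RMS trial) or after `max_trials` trials — a trial budget replaces
the wall-clock limit a human session would have, since simulated sessions
have no fatigue.

**Refinement.** Scaling each trial to unit RMS is only a first guess at
its scale; a trial showing a tight cluster of items legitimately uses the
arena differently from one showing a spread-out subset.  The final
estimator therefore alternates between (a) rescaling every trial by the
least-squares scalar aligning its distances to the current estimate on its
own pairs and (b) recomputing the evidence-weighted average from the
rescaled trials, normalizing the estimate to unit off-diagonal RMS each
round, until the estimate moves less than `tol = 1e-6` RMS or 50 rounds
pass.  With noiseless placements of a 2-D-embeddable geometry the estimate
equals the truth up to scale (Pearson r = 1 to machine precision); this is
the estimator's exactness anchor in the tests.

**Arrangement simulation.** Simulated positions come from classical
(Torgerson) scaling of the subset dissimilarities — deterministic and
closed-form, unlike iterative stress minimization — rescaled so the largest
pairwise distance spans 0.9 of the arena diameter.  If a skewed
configuration still reaches past the arena rim, the whole configuration is
shrunk uniformly (uniform scaling preserves distance ratios exactly;
clipping individual points would not).  Isotropic Gaussian jitter of scale
`placement_noise` models placement error; jittered points are clipped to
the disk.  Real human placement noise is surely structured (drag paths,
local crowding, serial order); the Gaussian model is a stand-in, so MA
recovery results on synthetic sessions bound estimator behavior under this
noise model only.

## Synthetic cohorts

Per-subject behavioral RDMs mix a shared source (the ground-truth
geometry's Euclidean RDM), an independent subject- or modality-specific
random geometry, and additive Gaussian noise truncated at zero, then
symmetrized.  All sources are rescaled to unit off-diagonal RMS before
mixing so weights are directly comparable; truncation keeps
dissimilarities nonnegative without modeling the arrangement process a
second time.  The two-modality generator gives the visual and linguistic
cohorts one common shared source and one unique source each, generated
independently — the configuration whose recovery the variance-partitioning
analysis is tested against.

Default cohort scale is 30 items, 12 behavioral subjects, and 8 synthetic
brain subjects on a 10×10×10 voxel grid: large enough to exercise every
code path (categories, adaptive subsets, fold structure, FDR over a
thousand centers) while the full pipeline runs in about a minute.

## Planted brain volumes

A region planted with a source RDM must reproduce that RDM under the
pipeline's own measure — correlation distance — which is a cosine, not a
Euclidean, quantity.  Projecting raw coordinates through a random loading
does not guarantee that (items far from the origin correlate highly with
everything).  The generator therefore embeds the source RDM by classical
scaling, lifts the configuration onto a sphere via a norm-equalizing extra
coordinate (sphere radius 3× the configuration's largest norm), and
projects through a random voxel loading with orthonormal, zero-sum
columns.  On the sphere, cosine distance is monotone in chord distance, and
the zero-sum orthonormal loading makes pattern correlations equal latent
cosines exactly, so the planted region's correlation-distance RDM matches
the source RDM's rank order (Spearman → 1 as noise → 0; the residual
distortion from the lift is O(spread²/radius²), a few percent of rank
variance at worst).  Signal is normalized to unit RMS times the region
amplitude; Gaussian voxel noise of scale `noise_sd` is added everywhere.

## Cross-validated NNLS reweighting

A "70:30 ratio using 10-fold cross-validation" cannot be a partition — ten
disjoint 30% test sets exceed the stimulus set — so a fold here is one
independent seeded random 70:30 item split, and ten of them form the
default plan.  Training uses only pairs with both items in the train set;
evaluation uses only pairs fully inside the test set; mixed pairs are
discarded, because a pair spanning the sets would leak test-item geometry
into the fit (the tests verify that physically deleting the test items
leaves fold weights bit-for-bit unchanged).  NNLS (via `scipy.optimize.nnls`,
the global optimum of the convex problem) has no intercept: the prediction
is a pure dot product of weights and predictor dissimilarities.  R² is
defined as (mean fold r)² — squaring the fold-averaged cross-validated
correlation — rather than the mean of per-fold r²; the alternative is a
one-line change and the choice matters only at third-decimal scale in the
synthetic experiments.  Cross-validated unique contributions
(R²_joint − R²_single) can be legitimately negative and are reported
as-is.

**Null calibration.** The calibration experiments shuffle the target's
pair vector itself, which destroys all representational structure and
isolates the spurious fit attributable to the machinery.  An
item-relabeling null is deliberately *not* used for this purpose: a
relabeled RDM of a category-structured geometry retains generic row and
block structure that genuinely correlates with the predictors, so it is
not an "unrelated target".  Item relabeling remains the inference null for
random-effects RSA, where items are exchangeable under the hypothesis
being tested.  At a 70:30 split the null spread scales with held-out pair
count: with 100 items each fold holds out 435 pairs and null fits stay
within |r| < 0.1; with 30 items a fold holds out only 36 pairs and the
same null spreads several times wider, so calibration statements are made
at the 100-item scale.

## Group statistics

Per-center fits are tested across subjects with a one-sample one-sided
*t*-test against zero (the direction of interest is behavior predicting
geometry, not the reverse); model-comparison tables accept an explicit
`sidedness` flag because two-sided tests are the convention for paired
model differences in some reporting styles.  BH-FDR is applied jointly
over all centers of a map (or all cells of a table) at q = 0.05, with no
finer spatial structure.  Paired fits that are exactly identical return
t = 0 with the corresponding tail probability rather than an error; a
constant *nonzero* paired difference is degenerate (zero variance with a
nonzero mean admits no t-statistic) and raises.

## Searchlight

Radius is measured in voxel units on an isotropic grid with inclusive
boundary (offsets with ‖Δ‖² ≤ r²).  Centers are all in-mask voxels;
neighborhoods keep only in-mask members, and centers with fewer than
`min_voxels = 10` members are dropped and reported — correlations over
very few voxels are unstable.  Zero-variance item patterns inside a
neighborhood raise under the strict policy (unit tests) and drop the
center with a report under the lenient policy (pipeline default).

## Pipeline and reproducibility

One global seed fans out into fixed-order per-stage seed streams
(ground truth, modality generator, MA sessions, brains, fold plan,
permutations); no stage touches global random state.  Output maps are
written as uncompressed `.nii` so artifact bytes carry no timestamps, and
the run manifest records a SHA-256 checksum per artifact: two runs with
the same config and seed produce identical checksums.  Stage timings live
only in the manifest, not in any data artifact.

## Known limitations

- The MA evidence rule (*w* = *d*²) and per-trial scale handling follow
  the weighted-averaging family of inverse-MDS estimators; other evidence
  functions are plausible and would change efficiency, not consistency.
- The generator's noise models (truncated Gaussian on dissimilarities,
  isotropic placement jitter, white voxel noise) omit known structure in
  real data — session drift, spatially correlated fMRI noise,
  heteroscedastic placement error — so passing recovery tests demonstrates
  correctness of the machinery, not performance guarantees on real
  cohorts.
- No noise-ceiling estimation, Kendall τ-a comparisons, ridge/OLS
  alternatives, or cluster-extent spatial inference.
- Volumes are isotropic grids; surface-based analysis is out of scope.
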