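# Methods

## Overview

`signedfc` compares three conventions for handling anti-correlations when
resting-state functional-connectivity matrices are binarized into brain
graphs, by measuring how each convention affects downstream case–control
classification under leave-one-site-out (LOSO) cross-validation.  The
pipeline is: ROI time series → Pearson correlation matrix → sign
transform (pos / neg / abs) → proportional threshold → binary graph →
graph-metric feature vector (optionally + PCA of the raw correlations) →
per-fold standardization → regularized MLP → per-site metrics →
aggregation and statistical comparison.

## Synthetic cohort model

Real multi-site rs-fMRI cannot ship with the package, so the study
conditions are emulated by a generative model that is itself tested code.

Each subject's regional activity is an N×T draw from a zero-mean
multivariate normal.  Regions are assigned round-robin to M modules
(deterministic, so unequal module sizes are reproducible).  The
population correlation is `within_module_corr` inside a module and a
group-dependent `between_module_corr_{hc,asd}` across modules; unit
variances make the correlation double as the covariance, which is then
scaled by the site's `noise_scale`.  Validity is enforced by an
eigenvalue check: smallest eigenvalue ≥ −1e−10 passes, drift down to
−1e−6 is repaired by eigenvalue clipping, anything worse raises an error
naming the offending parameters — silently repairing a grossly invalid
request would hide user error.  Sampling uses the eigendecomposition
square root, which stays stable for the (possibly singular) clipped
matrix.

The ASD−HC difference in between-module coupling is the planted,
topology-level group effect.  Defaults (M = 5, within 0.4, between 0.10
vs 0.20, T = 150) were chosen once as values typical of modular
functional-connectivity structure at conventional run lengths; tests and
the acceptance script construct their own explicit `CohortSpec`s rather
than leaning on these defaults.

**GSR.** Global signal removal is per-time-point subtraction of the
cross-region mean (the simplest estimator consistent with removing the
global mean from the signals); a flag switches to full regression of
each region on the global time series.  Mean subtraction makes every
column of the data sum to zero, hence every row of the empirical
covariance sums to zero, hence whenever any positive covariance exists at
least one strictly negative one must too — the anti-correlation regime
the sign pipelines are built for, guaranteed by construction rather than
by accident of sampling.

**Demographics.** The default template set mirrors the 17-site ABIDE I
cohort: per-site ASD/HC counts (1,035 subjects total), per-group sex
tallies, and age means/SDs pooled over the sex-stratified summary cells.
Ages are drawn per-site from a normal clipped below at `min_age`
(default 6 years).  Site effects beyond sample size, age distribution and
`noise_scale` (scanner/protocol differences, motion) are *not* modelled,
so passing tests demonstrate the machinery's correctness and calibration,
not robustness to real-world site confounds.

## Connectivity and thresholding

Pearson correlation of all region pairs (zero-variance regions are an
error naming the region).  The three sign transforms return nonnegative
weights with exact zeros treated as absent in all modes — a zero carries
no connection strength in any convention.

Proportional thresholding keeps the top `k = round(p · N(N−1)/2)` weights
(round half away from zero, fixed for cross-platform reproducibility).
The denominator is all node pairs, not just sign-retained pairs, so a
given p means the same graph density in every pipeline whenever enough
weights survive — threshold-matched comparisons between pipelines are
only meaningful at matched density.  If the sign filter leaves fewer than
k weights, all survivors become edges and a warning is recorded.  Ties at
the cut break lexicographically by (i, j), which also makes the edge sets
nested along the threshold grid.  The default grid is 0.20–0.50 in 0.02
steps (16 thresholds).

## Graph measures

Degree, clustering coefficient, transitivity, characteristic path length
(CPL), global and local efficiency, betweenness centrality (unnormalized
Brandes, endpoints excluded), eigenvector centrality, Louvain community
detection with participation coefficient and within-module degree
z-score, and degree assortativity.  networkx provides the standard
algorithms; participation coefficient and within-module z-score are
implemented directly (they are not in networkx) and everything is
verified against exhaustive brute-force oracles on small random graphs.

Degenerate-input conventions, fixed so feature matrices stay rectangular
and finite:

* proportional thresholds as low as 20 % can disconnect graphs, so CPL
  averages finite distances over reachable ordered pairs only, and
  efficiency counts unreachable pairs as 0 contribution;
* eigenvector centrality is computed by dense symmetric
  eigendecomposition on the largest connected component (nonnegative,
  unit norm), zeros elsewhere;
* assortativity of a degree-regular graph, z-scores in zero-spread
  modules, and eigenvector centrality of an edgeless graph are 0
  sentinels, each emission warned;
* within-module z-score uses the population SD (divide by module size).

Community detection seeds are derived from subject index and threshold
index so feature extraction is deterministic end to end.

## Features, PCA, standardization

The feature vector concatenates the 7 node metrics (N values each, fixed
registry order) then the 4 global metrics: 7N + 4 features, 1,404 at
N = 200.  This composition is a reconstruction from the stated metric
families and the printed total; the registry is explicit so alternative
compositions can be tested.

PCA operates on the strict upper triangle of the *raw* (untransformed)
correlation matrix, fitted inside each training fold only — fitting on
all subjects would leak test-site information into the loadings.  The
default 600 components are truncated to the feasible rank
min(n_train − 1, D) with a warning.  Standardization removes the
training-fold mean and scales to unit training-fold variance (population
convention); constant features map to 0.

## Classifier

Two hidden ReLU layers of 512 units; the first layer's weights carry an
L1 penalty (default 1e−3) to give the network feature-selection pressure
against ~1,400-dimensional inputs, the second an L2 penalty (default
1e−2); dropout 0.7 after each hidden layer; single sigmoid output.
Labels are HC = 1, ASD = 0, so downstream sensitivity reads as the
fraction of controls identified and specificity as the fraction of ASD
subjects identified.

Training minimizes BCE + l1·‖W₁‖₁ + l2·‖W₂‖₂² with minibatch Adam
(batch 32, initial learning rate 2e−4).  The Adam moment decays default
to β₁ = 0.99, β₂ = 0.01 — an unusually short second-moment memory that
makes updates nearly sign-like; `conventional_betas=True` restores
(0.9, 0.999) for sensitivity checks, and tests confirm both settings
learn separable data.  A class-stratified random 10 % of the training
subjects monitors validation loss (stratification prevents degenerate
single-class splits at small n); no improvement ≥ 1e−4 for 5 epochs
halves the learning rate, and after 3 decays without improvement training
stops and the best-validation weights are restored.  Epoch cap 200.  The
loop is plain NumPy (forward, backprop, Adam are a few dense products at
this width), which keeps training bitwise reproducible for a given seed.
The l1/l2 defaults are package choices exposed for tuning on a designated
held-out site, mirroring the single-site tuning discipline the evaluation
design assumes.

## Evaluation

One LOSO fold per site, ordered by site label; folds partition the
cohort exactly.  Nothing fitted in a fold touches its test site — an
explicit audit asserts the trained model is bit-identical when test-site
features are perturbed.  Each (site, pipeline, threshold) cell is
repeated (default 5; repetition r seeds the MLP with base_seed + r) to
average out initialization and validation-split noise.  Per-threshold
models are independent; no cross-threshold pooling.

Metrics at probability threshold 0.5; AUC is the Mann–Whitney rank
statistic with ties counted half (cross-checked against exhaustive pair
counting and scikit-learn).  One-class test sites yield an undefined-AUC
sentinel that aggregation excludes and counts.  Aggregation averages
repetitions within each threshold first, then takes mean and SD across
thresholds (the alternative ordering — pooling repetitions and thresholds
jointly — changes only the SD; the within-threshold-first convention is
the default and the one the comparison layer consumes).  The overall
"Mean" row is the unweighted mean of site means; "Weighted Mean" weights
sites by test-set size; the summary SD columns carry the corresponding
averages of the site SDs.

## Statistics

Welch's unequal-variance t-test (Welch–Satterthwaite dof, two-tailed)
compares pipelines per site on trial-level threshold-averaged metrics,
and per (site, threshold) cell on repetitions; paired t-tests across
sites compare site-mean metrics per pipeline pair.  Two identical
constant samples return t = 0, p = 1 (a defined no-difference case);
all-zero paired differences likewise.  Holm–Šidák correction
(step-down 1 − (1 − p)^(m−i+1) with running maximum) is applied within
each metric inside each comparison type — the family delimitation is a
package choice, configurable by calling the pieces directly, since
nothing forces one delimitation over another.  Simulation tests confirm
family-wise error control under a global null.

The site-performance-vs-age analysis is OLS of site AUC on
(1, age, age²) with R² and the overall F-test p-value; degree 3 is
available since a cubic can fit age profiles the quadratic misses.  It
requires more distinct age values than the polynomial degree.

## Problem sizes and determinism

Unit and acceptance tests run the full stack at reduced scale chosen to
keep the signal honestly recoverable: the planted-effect check uses 4
sites × (20 ASD + 20 HC), 20 regions, 4 modules, T = 300, between-module
difference 0.4 — conditions under which a logistic-regression oracle
confirms the features are separable before the MLP is asked to
generalize across sites.  Chance calibration uses the same generator
with permuted diagnosis labels over 20 repetitions.  Statistical
calibration uses 500 simulated null families.  Every random draw in the
package flows through an explicit seed or `numpy.random.Generator`;
identical seeds give byte-identical cohorts, features, and trained
models on a fixed platform.

## Known limitations

* The generator's site effects are limited to sample size, age
  distribution, and a noise scale; no motion, physiological nuisance, or
  scanner-protocol structure, and no image-space simulation.
* Graph measures cover binary undirected graphs only — no weighted or
  directed variants, no small-worldness or rich-club normalization.
* The 7N + 4 feature composition is a documented reconstruction, not a
  uniquely determined fact; the registry is explicit so it can be varied.
* Holm–Šidák assumes independence-like positive dependence within a
  family; with strongly correlated metrics the correction is
  conservative.
* Conclusions from synthetic cohorts transfer to real data only insofar
  as the block-covariance + GSR model captures the relevant structure;
  the package demonstrates methodology, not clinical performance.
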