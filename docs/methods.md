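# Methods

This note documents the models implemented in `cytoconn`, the choices made
where the underlying methodology leaves room, and what the synthetic
validation does and does not establish.

## Motion model and scrubbing

Per-volume motion is summarised from rigid-body transforms expressed
relative to the first (reference) volume. Euler angles are extracted in the
intrinsic Z-Y-X convention (the choice is internal: all contracts are tested
through round-trip identities). The scalar displacement is

    d = |Tx| + |Ty| + |Tz| + |θx|·r_z + |θy|·r_z + |θz|·r_x

with effective radii r_x = r_y = r_z = 5 mm by default (a mouse brain is
roughly a 5 mm sphere; the radii are configurable). Two deliberate points:
absolute values are taken on all six terms so the result is a non-negative
displacement, and the second rotational term multiplies θ_y by r_z even
though θ_y·r_y would be the geometrically expected pairing — a deliberate
convention, flagged to users, that is inconsequential under the isotropic
default radii where the two coincide. Volumes with d > 0.125 mm (half an in-plane voxel) are censored
together with one neighbour on each side; scans keeping < 90 % of volumes
are dropped.

## Preprocessing

Nuisance regression is ordinary least squares of each ROI course on an
intercept, a WM-CSF-style global regressor, and the six rigid motion
parameters, computed over retained volumes only; the design is checked for
collinearity and rank-deficient designs are rejected naming the offending
columns. Spatial smoothing uses a normalised 3×3 Gaussian kernel with
σ = 0.7 px (the kernel size is prescribed, σ is not; 0.7 px puts ≈ 90 % of
the mass inside the 3×3 footprint) and renormalises by in-mask kernel mass
so constant images are preserved at edges. Temporal filtering is a
zero-phase 4th-order Butterworth band-pass, 0.01–0.1 Hz; censored volumes
are linearly interpolated before filtering to avoid ringing at gaps and
remain censored afterwards, so they never enter the correlation. Pairwise
Pearson correlation over retained volumes (minimum 30) yields the
connectivity matrix; zero-variance ROIs become missing rows/columns rather
than failing the scan, and missingness propagates pairwise.

## Connectivity statistics

All averaging and differencing of correlations happens in Fisher-z space:
system-level values are tanh(mean(arctanh r)) over the relevant ROI pairs
(within-system diagonals exclude self-pairs), group means are entrywise
z-means, difference matrices are reported in z units. Correlations of
exactly ±1 (possible only for degenerate/duplicated ROIs) are clipped to
±(1 − 1e−10) before arctanh.

Edgewise group contrasts fit, per edge, a linear mixed model with the
z-transformed correlation as response, genotype (plus age and genotype×age
in longitudinal mode) as fixed effects and a per-subject random intercept
(REML, via statsmodels MixedLM). Repeated scans of a subject enter as
repeated rows under the random effect. The genotype coefficient is tested
two-tailed with residual degrees of freedom (n − p); measured under the
null synthetic generator this choice keeps the edge-level false-positive
rate near nominal (≈ 4–7 % at α = 0.05). Singular mixed fits fall back to
OLS and are flagged in the output. FDR correction is Benjamini–Hochberg
within one comparison family (all edges of one timepoint's contrast). The
two significance thresholds used for masks (0.05, and 0.005 for stricter
displays) are exposed as parameters rather than hard-coded.

## Graph metrics

Connectivity matrices become weighted graphs with w = |r| off-diagonal.
Strength, Onnela clustering, characteristic path length, global efficiency
and betweenness follow the standard weighted definitions (see README for
formulas). Choices worth stating:

- **Weight→length mapping.** Shortest paths use lengths 1/w. This is the
  standard convention for correlation-weighted brain graphs but it is a
  choice, not a theorem; all path-derived quantities inherit it.
- **Clustering normalisation.** Weights are divided by the maximum weight
  before the geometric-mean triangle term (Onnela convention), bounding
  C_i ≤ 1. Exposed as a flag (default on).
- **Assortativity.** Implemented as the Pearson correlation of endpoint
  weighted degrees across edges (the Brain Connectivity Toolbox weighted
  form). This form is invariant under uniform weight scaling and reduces to
  classic binary assortativity for 0/1 weights; it returns NaN when all
  endpoint degrees coincide (zero variance).
- **Disconnected graphs.** Efficiency uses 1/∞ = 0 for unreachable pairs;
  the characteristic path length is reported as infinite with a
  finite-pairs fallback value alongside.
- **Hub scores.** On a group-average graph each node earns one point per
  criterion: strength ≥ 80th percentile, betweenness ≥ 80th percentile,
  mean shortest-path distance ≤ 20th percentile, clustering ≤ 20th
  percentile (the low-clustering criterion is an unusual but deliberate
  convention of the hub definition used here, although
  high-strength hubs often have low clustering for mechanical reasons).
  Percentiles use linear interpolation; threshold ties qualify. Per-node
  "path length" is the mean distance to all other nodes (nodal eccentricity
  would be the alternative reading; mean distance is the common one).

## Cytokine cleaning

Censoring maps concentrations below the standard curve's lower limit to
0 pg/mL and above the upper limit to the curve maximum (idempotent).
Retention keeps an analyte when it is non-zero ("above background" — after
censoring, below-limit values are exactly 0) in ≥ 50 % of the subjects in
the modelling stratum (region × group), with an exception for analytes
whose non-zero values skew toward one genotype. "Skewed toward one
genotype" has no canonical quantitative form; it is operationalised here
as the smaller of the two one-sided Fisher exact p-values on the 2×2
genotype × detectability table, retained when p < 0.10 (threshold
configurable). Every decision is recorded with its rule in an audit table.

## PLS modelling

PLS is implemented from scratch (NIPALS, univariate response): weights
w_a ∝ X'y with deflation of X (and y) per component; scores are mutually
orthogonal by construction. Covariates are z-scored; the response is age in
months (regression) or a −1/+1 class code with classification by predicted
sign (discriminant analysis; the design is two-group throughout).
Components are oriented so the first y-loading is positive, making positive
LV1 loadings read as "up with the response". NIPALS tolerance is 1e−10
with a 500-iteration cap (one pass suffices for a univariate response);
ties in model selection break toward fewer components.

**Orthogonalization.** Fitted A-component models are re-expressed O-PLS
style: A−1 response-orthogonal components are peeled off the covariate
matrix, then a single predictive component is fitted to the filtered
matrix. For a univariate response this leaves predictions numerically
identical (asserted at 1e−8 in the tests) while concentrating all
predictive covariance on LV1, which is what the signature report reads.

**VIP.** Standard Wold VIP,
`VIP_f = sqrt(p · Σ_a SSY_a (w_fa/||w_a||)² / Σ_a SSY_a)` with
SSY_a = q_a² t_a't_a; mean squared VIP is identically 1, so Wold's variant
is the one under which "VIP > 1" reads exactly as an above-average
contribution. For an orthogonalized model the VIP of the underlying
non-orthogonalized fit is reported.

**Cross-validation.** k = 3 folds when n > 30, else k = 5; the unassigned
boundary n = 30 maps to k = 5 (more training data per fold). 100 random
repartitions; candidates A ∈ {1, 2, 3}; per training fold the z-scoring is
refit (leakage-safe — whether the original analysis rescaled inside folds
is unstated; refitting is the conservative reading). The per-repeat
statistic is RMSECV = sqrt(mean((pred − y)²)) over the pooled held-out
predictions, or accuracy for discriminant models. Discriminant folds whose
training half lacks a class are reshuffled (logged).

**Permutation significance.** The response is shuffled against the
covariate rows; the cross-validated statistic at the chosen A is recomputed
per permutation; Z = (x_model − μ_null)/σ_null with a one-tailed
normal-tail p in the favourable direction (lower RMSECV / higher accuracy).
Running the full 100-repeat CV inside every one of 1000 permutations is
computationally disproportionate at any scale, so the permutation statistic
uses a reduced repeat count (default 10; the observed statistic is
recomputed with the same count so observed and null values are exchangeable
under the null). Null p-values are approximately uniform under
independence (KS distance ≈ 0.08 over 100 null datasets in the acceptance
suite). Note the normal-tail p is conservative when the null RMSECV
distribution is right-skewed, which it typically is; σ_null = 0 yields a
NaN (undefined) result.

## Synthetic generator: what it emulates, and what it does not

The generator reproduces the study design — two genotypes × four ages
(1.5, 2, 4, 6 months), several scans per subject and session, TR 1.5 s —
and the statistical structure the pipeline assumes:

- ROI time series are multivariate normal with a block correlation target
  (within-system 0.6, between-system 0.2 by default). The disease effect is
  an additive shift in Fisher-z space (−0.3 by default) on designated
  system blocks at designated ages (hippocampal and thalamic blocks at 4
  and 6 months), and subjects carry a z-space random intercept (SD 0.1).
  Applying effects in z-space and back-transforming guarantees valid
  correlation matrices; the block target is repaired to the nearest
  positive-definite matrix by eigenvalue clipping at 1e−8, and structurally
  indefinite targets (minimum eigenvalue < −1e−3) are rejected with a
  diagnostic.
- Motion traces are sub-threshold uniform jitter plus Bernoulli spikes
  (2 %/volume by default). With the ±1-neighbour censor rule this discards
  ≈ 6 % of volumes, so the large majority of scans clear the 90 % retention
  rule — emulating a habituated awake-imaging session. Ground-truth spike
  indices are recorded.
- Cytokine panels are log-normal (23 analytes named after the multiplex
  panel), with three planted analytes (MIP-1α, MIP-1β, KC) whose
  log-concentration rises 0.5 SD per month of age in the disease genotype,
  and detection limits of 1–10⁴ pg/mL.

It does **not** simulate image physics, hemodynamics, spatial structure
(ROI time courses are generated directly), plate effects or standard-curve
fitting, non-Gaussian BOLD noise, autocorrelated time series, or
dropout/attrition. Consequently the passing tests establish internal
correctness and statistical calibration of the *analysis* — exact
agreement with brute-force oracles, nominal false-positive rates, recovery
of planted effects at the design's size — not robustness to the artefact
structure of real scanner data.

## Problem sizes in the validation suite

The acceptance checks run at deliberately scaled sizes chosen to exercise
the full design while keeping the suite fast: calibration of the edgewise
contrast uses 100 null datasets of 12 ROIs (4 systems), 8 subjects per
genotype, 2 scans of 120 volumes; planted-block recovery uses 20 replicates
at the default −0.3 z effect; cytokine recovery uses 50 replicates of the
23-analyte, n = 26 design; permutation calibration uses 100 null datasets
at 200 permutations. The end-to-end pipeline default
(`cytoconn.pipeline.DEFAULT_PIPELINE_CONFIG`) is 6 subjects per genotype,
16 ROIs in 4 systems, 2 scans × 200 volumes across all four ages.

## Known limitations

- The mixed-model t test uses residual degrees of freedom; with few
  subjects and many scans per subject this is mildly liberal for
  between-subject effects (Satterthwaite/Kenward-Roger approximations are
  not available in the fitting backend). Measured calibration at the
  design's sizes stays near nominal.
- The permutation Z assumes an approximately normal null; for small n the
  skew of RMSECV makes the test conservative rather than anticonservative.
- NIfTI volume input is not implemented; ROI-labelled matrices (TSV +
  manifest) are the supported input format. In-plane smoothing is provided
  for array input but the shipped pipeline operates on ROI time series.
- PLS-DA is two-class only, matching the genotype design.
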