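# Methods

## Model and estimator

The analysis relates two subject-aligned feature matrices: `X` (n subjects
x p brain regions, betweenness centrality of a weighted functional
connectome) and `Y` (n x q questionnaire responses, binary or ordinal).
Columns of both are standardized to zero mean and unit sample variance
(ddof = 1) before fitting; standardization is on by default and uses
training-fold parameters wherever held-out data are scored.

The estimator is the penalized-matrix-decomposition form of sparse CCA:

    max_{u,v}  u' X' Y v
    s.t.       ||u||_2 <= 1,  ||v||_2 <= 1,
               ||u||_1 <= c1, ||v||_1 <= c2 .

The exact CCA scale constraints `u' X'X u <= 1` are replaced by unit L2
norms (the "diagonal approximation"): with p = 246 regions and training
folds of ~200-240 subjects, `X'X` is singular and its inverse square root
undefined, so the diagonal approximation is the standard and defensible
treatment. A sensitivity knob `covariance="regularized"` rescales each
update direction to `u' B u = 1` with `B = (1 - a) I + a X'X / n`
(default `a = 0.1`); this variant is approximate — the exact subproblem
with both an L1 budget and an ellipsoidal scale constraint has no closed
form — and exists for robustness checks only.

### Alternating updates

For fixed `v`, the maximizer of `u' (X'Y v)` over the constraint set is

    u = soft(X'Y v, delta) / ||soft(X'Y v, delta)||_2 ,

elementwise soft-thresholding with the smallest `delta >= 0` whose
normalized result satisfies the L1 budget. `delta` is found by bisection on
`[0, max|X'Y v|]` (60 iterations; the bracket halves to ~1e-18 of its
width, keeping the objective trace monotone to well below 1e-10). The `v`
update is symmetric. Updates alternate until the max loading change falls
below `tol = 1e-6` or 200 iterations.

Entries below 1e-12 of the largest loading magnitude are snapped to exact
zero so that "selected feature" (nonzero loading) is crisp rather than a
floating-point accident.

### Initialization and multi-start

Coordinate ascent on a bilinear objective has fixed points that are not
global when the L1 budget binds hard. The solver therefore runs from five
deterministic, data-derived starts — the leading right singular vector of
`X'Y` (exact in the unpenalized limit), the two largest rows of `X'Y`
normalized (the best row is provably the global optimum in the 1-sparse
limit `c1 = 1`), and the indicators of the two largest columns — and keeps
the highest final objective. No randomness enters the solver; seeds affect
data only.

### Sign convention

Canonical loadings are defined up to a joint sign flip. The largest-|u|
entry is made positive and `v` follows so the objective stays nonnegative;
signed loadings are then interpretable (positive regions co-vary with
positively-loaded questions).

### Budget vs. Lagrange parameterization

Budgets `(c1, c2)` in `[1, sqrt(dim)]` are the primary parameterization;
below 1 the feasible set under the unit-L2 scale collapses, above
`sqrt(dim)` the budget is inactive. The soft-threshold level the bisection
lands on is the implied Lagrange weight of the equivalent penalized form
and is reported per fit (`delta_u`, `delta_v`).

## Connectome construction

Pearson correlations of ROI time-series pairs define edge affinities.
Soft thresholding `((r + 1) / 2) ** beta` with integer `beta >= 1`
(default 6) maps [-1, 1] monotonically onto [0, 1], emphasizing strong
edges without a hard cutoff; Fisher's `atanh` then spreads the upper range
(clipped at `1 - 1e-7`, where it diverges). Betweenness uses edge length
`1 / weight` — the standard convention for connectivity-strength graphs —
with weights below 1e-12 treated as absent edges (their reciprocal lengths
would otherwise dominate all paths), unnormalized Brandes path counting,
fractional credit under ties, endpoints excluded. Normalization is omitted
because columns are standardized downstream anyway.

## Penalty tuning

Subjects are partitioned into k seeded folds (default 5; the
small-cohort/ordinal preset uses 3). For every grid point the model is fit
on the training rows (training-only standardization) and scored by the
Pearson correlation of the held-out variates. The default grid is 12 x 12
log-spaced budgets over `[1, sqrt(p)] x [1, sqrt(q)]`; a coarser grid
under-resolves the region where the optimal budget sits.

The held-out correlation curve is nearly flat past the optimal sparsity,
so a plain per-fold argmax drifts into needlessly dense models on sampling
noise. Each fold therefore picks the *sparsest* grid point within
`se_rule = 0.75` standard errors of its maximum, with the SE taken from
the Fisher variance of a sample correlation, `(1 - rho^2) / sqrt(n_test -
3)`. Setting `se_rule = 0` recovers the plain argmax (exact ties still
resolve to the sparser model). The 0.75 multiplier was calibrated on
planted-recovery experiments: at reference conditions (n = 300, p = 246,
q = 51, 10 + 8 planted features, effect 3, noise 1) it recovers >= 80% of
the support with >= 80% precision in ~85% of seeds, whereas argmax
achieves full recall but 8-55% precision, and a full 1-SE step loses
recall. Final budgets are the component-wise fold average, and the final
model is fit on the full data with full-data standardization.

## Bootstrap stability selection

"Resampling 80% of subjects" is implemented as subsampling *without*
replacement (each replicate draws `floor(0.8 n)` distinct subjects); a
`with_replacement` flag provides the classical bootstrap of the same size
for sensitivity. Each replicate refits at the fixed tuned budgets; a
feature counts as selected when its loading is nonzero. The top-k most
frequently selected features (k = the full-data fit's selection size; ties
broken by larger mean |loading| across replicates) are intersected with
the full-data selection and reported as an overlap count and percentage.

## Post-hoc clinical association

Stage 1 averages the centrality of the selected regions within each
behavioral domain and correlates each domain average with each clinical
score (two-sided p from the exact t reference with n - 2 df).
Benjamini-Hochberg adjustment is applied within each score's family of
domain tests (a pooled-family option exists; the per-score default mirrors
how such results are conventionally tabulated per score). Stage 2 tests
the member regions of each significant (domain, score) pair against that
score, FDR within the family; this gatekeeping is configurable off.
BH is implemented directly (sort, `m p_(j) / j`, backward minimum, cap at
1) so the step-up definition holds bit-exactly.

## Synthetic data

`generate_coupled_dataset` plants a rank-1 cross-structure: a latent
factor `z_i ~ N(0,1)` per subject, support columns of `X` equal
`lambda * u_j * z + noise`, and support columns of `Y` are monotone
discretizations of the same construction — a median split for binary
responses (balanced 0/1, the most informative binarization) and quartile
bins for ordinal 0-3 responses. Off-support columns are independent noise
passed through the same marginal transform. Noise is i.i.d. Gaussian, the
maximum-entropy choice that keeps oracle quantities closed-form (e.g. the
population canonical correlation under binarization follows from
`E[c 1{c>0}]` and orthant-probability identities, which the tests use).

Planted loading magnitudes are drawn uniform on [0.7, 1] with random
signs, then normalized. Discretization compresses response-side loading
magnitudes toward equality at strong signal, so widely dispersed
magnitudes would make the planted direction unrecoverable *in principle*;
the narrow band keeps every planted feature carrying comparable signal and
the truth recoverable (leading singular vectors of centered `X'Y` align
with the truth to cosine >= 0.95 at lambda/noise >= 10).

Clinical scores are constructed by exact projection: the score is
`rho * m_hat + sqrt(1 - rho^2) * e_hat` with `m_hat` the centered,
normalized target-region mean centrality and `e_hat` orthogonalized
Gaussian noise, so the sample correlation equals `rho` exactly and
post-hoc tests have deterministic inputs.

`generate_roi_timeseries` emulates modular resting-state structure only:
regions in a module share a latent signal scaled so the expected pairwise
within-module correlation equals the target. It does not model
hemodynamics, scanner noise spectra, autocorrelation, or head motion —
passing tests on these fixtures validates the graph pipeline's
arithmetic, not its robustness to realistic fMRI artifacts. Likewise the
Gaussian marginals of the synthetic centrality columns are a modeling
choice; empirical betweenness distributions are heavy-tailed, and no claim
of distributional realism is made.

## Determinism

Every generator is a pure function of its arguments including the seed.
The pipeline derives all stage seeds from one master seed, keeps wall-clock
timings out of the numeric report, and materializes every matrix
C-contiguously before BLAS calls (kernel selection depends on memory
layout, and a table parsed from disk must reproduce an in-memory run
bit-for-bit). Tables are written at full float precision and parsed back
with round-trip float handling, so centrality-mode runs on a written
centrality table equal the timeseries-mode runs that produced it.

## Problem sizes in the validation suite

The test suite validates oracle agreement on small problems (graphs of <=
8 nodes against exhaustive path enumeration; 3 x 2-feature SCCA against a
dense hierarchically-refined grid search), recovery and calibration at the
reference scale (n = 284-300, p = 246, q = 51) over 10-20 seeds, null
calibration of the post-hoc FDR over 200 replicates, and bootstrap
discrimination at a reduced scale (p = 60, 200 replicates, 10 seeds).
The demo configuration lowers the bootstrap count to 200 (the full 1000 is
one config edit away).

## Known limitations

- Single canonical component; no deflation for further components.
- The regularized-covariance mode is an approximate sensitivity knob, not
  an exact solver.
- Penalty tuning reports no unbiased performance estimate (no nested CV),
  matching the single-evaluation design it reimplements.
- Betweenness on near-disconnected graphs depends on the 1e-12 edge
  cutoff; centrality of isolated nodes is 0.
- The synthetic generator's rank-1 latent structure is the assumed model
  of the estimator; it quantifies recovery under the model, not model
  misspecification.
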