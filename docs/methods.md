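# Methods

This note records the modeling procedures, the defaults and the design
choices made where the procedure itself leaves room, in enough detail to
reimplement the package from scratch.

## Data model and preparation

An observation is one ionic-liquid cation: an identifier, a SMILES string
(charge included; covalently linked di-cations are one molecular graph) and
a measured log₁₀ partition coefficient at 298 K.  The anion is constant
within a series and never featurized.  Descriptors are numeric 2D features
computed by a pluggable engine (`compute_descriptors` fixes only the matrix
contract: one row per cation, the engine's column set, non-finite outputs
stored as NaN).  The shipped engine is RDKit's 2D descriptor list (~210
columns); any mapping SMILES → ordered name/value pairs can be substituted.

Pruning runs three passes in a fixed order: columns containing any
non-finite value are dropped (column, never row — n is the scarce
resource); zero-variance columns are dropped; then, scanning the survivors
in input order, a column whose |Pearson r| with an already-retained column
reaches the threshold is dropped, recording its partner.  The threshold
defaults to 0.95 and is configurable, because the collinearity criterion is
a genuine free parameter of this workflow and retained-descriptor counts
depend on it.  First-in-input-order wins all ties, making the result
deterministic with no randomness.

Standardization maps each surviving column to mean 0 and sample sd 1
(ddof = 1) using full-series statistics computed once, before fold
splitting, and stores the means/sds for application to new cations.
Computing the statistics before splitting leaks a small amount of held-out
information into each fold's model; this mirrors the prepare-then-split
workflow the package implements and is documented rather than "fixed".

Folds are deterministic: cations are ranked by log K (ties broken by input
order, stable sort) and rank j goes to fold j mod n_folds (default 10).
Every fold therefore spans the full response range and fold sizes differ by
at most one (n = 57 gives seven folds of 6 and three of 5).

## Linear models

OLS is fit with an explicit intercept column; a rank-deficient design fails
naming the dependent columns (QR with column pivoting).  On standardized
descriptors the intercept equals mean(y).

OMP is the classical refit variant: starting from the intercept-only
residual, add the descriptor with maximal |Pearson correlation| to the
current residual, refit OLS on the active set, recompute the residual;
never re-add a descriptor; stop at the requested size, or early (with a
smaller model) if the residual reaches numerical zero.

The expulsion search widens OMP's horizon.  Each round runs OMP on the
current pool and records the candidate with its 10-fold cross-validated r²
(training r² is available as a config option; cross-validated is the
default because it is the criterion the rest of the pipeline optimizes).
If the pool still holds a descriptor with |corr(Xⱼ, y)| ≥ 0.4 (default
threshold), that descriptor is expelled from the *pool only* and the next
round begins; when the maximum correlation falls below the threshold the
search stops without a further OMP run.  Candidates keep their own
descriptors even when those are later expelled — expulsion shapes the
search space, not the models.  Highest cv r² wins, earliest round on ties.

Model size for every family follows the same rule: grow from k = 1 and
accept k+1 iff (err_k − err_{k+1})/err_k ≥ 0.20 with err = 1 − cv r²; the
first rejection (or k_max, default 5) stops growth.  Exactly 20 % is
accepted (≥).

## Kernel models

SVR uses the ε-insensitive loss with the squared-exponential kernel
K(x,x′) = exp(−γ‖x−x′‖²).  The quadratic program is delegated to
scikit-learn's SMO solver; the module contract fixes the loss, the kernel
and the γ-token semantics ("auto" → 1/p; "scale" → 1/(p·Var(X)) with Var
over all matrix entries).  Tests verify the duals against a generic SLSQP
solution of the dual QP.  During descriptor selection the hyperparameters
are held at C = 1, ε = 0.001, γ = "auto"; the exhaustive grid — C ∈
{0.001, 0.005, 0.1, 0.5, 1, 5, 10, 50, 100, 500, 1000}, ε ∈ {0.001, 0.005,
0.01, 0.05, 0.1, 0.5, 1, 5, 10}, γ ∈ {0.001, 0.005, 0.01, 0.05, 0.1, auto,
scale} — is searched only on the concluded descriptor set, by cross-validated
r² with first-in-grid winning ties.

GPR uses the kernel sum σ₀² + x·x′ + exp(−‖x−x′‖²/2ℓ²) + σ_n²·δ (dot
product + squared exponential + white noise).  Fitting maximizes the log
marginal likelihood by L-BFGS from the given initialization plus seeded
log-uniform restarts (5 for final fits; 0 restarts — a single optimized
start — per candidate during descriptor selection, for tractability).
Cholesky jitter escalates 1e-10 → 1e-8 → 1e-6 before the fit is declared
ill-conditioned.  Predictive mean and covariance are the standard GP
conditionals; the predictive covariance includes the white-noise term on
its diagonal (it predicts observations, not latent values).

Both kernel families share greedy-substitution selection: a forward step
adds the pool descriptor with the best cv r²; then substitution passes try
every (position, replacement) pair and adopt the single largest strictly
improving swap, repeating until no swap improves; then the next forward
step.  Positions are scanned in selection order; subset scores are memoized
so no subset is evaluated twice.  By construction the result is never worse
than pure forward selection.

## Evaluation

r² = 1 − SS_res/SS_tot (negative when the model underperforms the mean);
RMSE; and Lin's CCC = 2·cov(y,ŷ)/(var(y)+var(ŷ)+(ȳ−ŷ̄)²) with the
n-denominator convention in numerator and denominator (the convention
choice cancels in the ratio only if applied consistently, which this is).
Inside the CV harness a constant prediction vector receives its limiting
CCC of 0 rather than an error; the standalone `ccc` is strict.

Cross-validation statistics are reported in two modes: the headline
aggregate is the unweighted mean of per-fold statistics; pooled out-of-fold
statistics are computed alongside because the two answer slightly different
questions and disagree whenever folds differ in response spread.

Permutation importance is the mean r² decrease over n_repeats = 30 seeded
shuffles of one column, scored on the data the model was fitted to, without
refitting.  Values above 1 are expected for dominant descriptors (the
permuted r² goes negative).  Each column's permutation stream is seeded
from (seed, descriptor name), so a descriptor's importance is invariant to
the placement and naming of the other columns.

## Influence diagnostics (linear models only)

Leverage is the hat-matrix diagonal of the design with intercept; high
threshold 3(k+1)/n, moderate threshold 2(k+1)/n (the conventional
companion; configurable).  Residuals are internally studentized with the
single global σ̂² = eᵀe/(n−k−1) and e = y − ŷ; the reported sign is
ŷ − y (positive = over-prediction).  |r| > 2 is a moderate residual,
|r| > 3 a likely outlier.  Cook's distance D = r²/(k+1) · h/(1−h); D > 1
flags an influential observation.  Points with leverage numerically 1 get
NaN residuals (flagged as undefined) rather than infinities, and a
numerically perfect fit returns all-zero residuals instead of 0/0 noise.
The influence report groups observations by flag and exports the influence
plot's scatter data (leverage vs standardized residual, point size ∝ D).

## Synthetic data

The generator emulates the statistical shape of a small QSPR campaign, not
its chemistry: defaults are n = 60 observations, p = 200 base descriptors
in correlated blocks of 5 (within-block ρ = 0.5, block factor model), a
planted 4-descriptor signal with standardized coefficients
(1.0, −0.8, 0.6, −0.4) placed in distinct blocks, 5 collinear decoys
(|r| ≈ 0.995 copies of signal columns), 5 constant decoys, and Gaussian
noise whose sd is computed in closed form — σ = √(Σβ²·(1−r²)/r²), valid
because the signal columns are independent by construction — to hit a
population r² of 0.9, matching the performance regime of real
gas–IL partition models.  The nonlinear variant adds a unit-variance
interaction a·X₁X₂ (default a = 1) that no linear model can represent,
keeping the closed-form calibration (the interaction is uncorrelated with
the linear part).  Anomaly injection appends rows with signal descriptors
at ±4 sd (high leverage, on-surface response) and rows with the response
shifted by 5 noise sd (high residual), recording their indices.

Because columns are population-standardized draws, sample means/sds differ
slightly from 0/1 and the preparation stage still does real work.  What the
generator does *not* emulate: real descriptor distributions (heavy tails,
integer counts, zero inflation), structured missingness, measurement error
in y correlated with structure, and activity cliffs.  Passing tests
therefore demonstrate the correctness and the statistical behavior of the
procedures under the stated generative model, not chemical validity on any
particular experimental series.

## Pipeline and reproducibility

A run is configured by one YAML document (method, thresholds, grid, seed,
paths); the seed derives per-stage seeds by fixed offsets (+202 GPR
optimizer, +303 permutation importance).  Artifacts (model, fold stats,
importances, influence tables, prediction scatter, removal log) are JSON/CSV
stamped with the seed and a hash of the canonical config; identical configs
reproduce byte-identical JSON.  Human-readable reports print at 3 decimals;
JSON keeps full precision.

The acceptance script reports the recovery study at its reference
conditions (n = 60, p = 150, 50 replicates) and demonstrates the SVR/GPR
pipelines on a 60 × 40 pool with k_max = 4 — a size chosen so a
demonstration run completes in about a minute while still exercising
selection, substitution, grid tuning and kernel optimization end to end.

## Known limitations

* The expulsion loop expels by correlation to y only; descriptors masking a
  signal through multivariate relationships are not targeted.
* GPR candidate scoring optimizes the kernel from a single start per fold;
  occasionally a fold lands in a poor local optimum of the marginal
  likelihood, which shows up as a pessimistic cv score for that subset.
* Influence diagnostics apply to the linear family only; kernel-model
  analogues (e.g. ad-hoc leverage in feature space) are out of scope.
* Reproducing published per-series statistics requires the deposited study
  archive; without it the package validates against oracles and planted
  synthetic truth.
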