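# Methods

## Model and optimization

The selector regresses one-hot class indicators `Y ∈ {0,1}^{n×c}` on the
transposed feature matrix `Xᵀ ∈ R^{n×d}` with an ℓ2,1 loss and an ℓ2,1
penalty on the transformation `W ∈ R^{d×c}`:

    min_W (1/θ)·||XᵀW − Y||_{2,1} + ||W||_{2,1}.

Both terms sum Euclidean row norms, so the loss is robust across samples
and the penalty is jointly sparse across classes.  Introducing
`Q = (Y − XᵀW)/θ` gives the equivalent constrained program
`min ||[W;Q]||_{2,1} s.t. [Xᵀ, θI][W;Q] = Y`.  Because the `θI` block
makes `K = [Xᵀ, θI]` full row rank for any data whenever θ > 0, the
closed-form iteratively-reweighted update

    V ← G⁻¹Kᵀ(KG⁻¹Kᵀ)⁻¹Y,   g_ii = 1/(2·sqrt(||vⁱ||² + δ)),

always exists.  `G` starts at the identity (the first iterate is the
minimum-Frobenius-norm feasible point) and is stored as a diagonal
vector only.  Every iterate is exactly feasible by construction, and the
update is a majorize–minimize step on the smoothed objective
`Σ_i sqrt(||vⁱ||² + δ)`, which is therefore non-increasing — both
properties are asserted over random ensembles in the test suite, and the
solution is checked against an independent convex reference
(null-space parametrization of the feasible set + L-BFGS on the smoothed
objective) to 1e-3 relative objective.

Numerical choices:

- **Smoothing δ** (default 1e-12): removes the division by zero of the
  row-weight update at all-zero rows; the fixed point is unchanged as
  δ → 0.  A consequence of finite smoothing plus finite iterations is
  that "zeroed" rows are small but not exactly zero; effective sparsity
  is therefore graded by row-norm magnitude, not exact zeros.
- **Convergence**: stop when the absolute objective change falls below
  `tol` (default 1e-6) or after `max_iter` (default 100) steps.  No
  reference value for the stopping threshold exists for this model
  family; both knobs are exposed.
- **Inner solve**: `KG⁻¹Kᵀ` is symmetric positive definite, solved by
  Cholesky with one retry adding `1e-10·trace` jitter.  A large residual
  after the first closed-form update signals a rank-deficient or
  inconsistent system and raises immediately rather than returning an
  infeasible "solution".

## Stacked refinement

The stacked model fits a base layer (previous output zero, hence plain
E-JS), then `m` refinement layers.  Layer `s` draws a fresh projection
`Z_s ∈ [0,1]^{c×d}` with i.i.d. uniform entries from one seeded
generator stream, shifts the input to `Xᵀ + σ·Y_{s−1}Z_s` with
`Y_{s−1} = XᵀW_{s−1}`, re-fits, and propagates its own output.  Design
choices made where the procedure was genuinely open:

- **Layer count**: one pre-loop fit plus `m` loop fits, i.e. `m + 1`
  layers total; the `m + 1` reading is adopted and documented rather
  than asserted as canonical.
- **Final ranking** comes from the last layer's `W`; intermediate `W_s`
  are retained for diagnostics.
- **σ default 0.1**: no reference value exists for the shift strength;
  0.1 keeps the shift norm well below the input norm at the package's
  default scales.  A runtime warning flags shifts whose Frobenius norm
  exceeds the input's — the distortion regime in which stacking too
  aggressively harms rather than helps.
- **Ranking statistic**: the row-wise ℓ2 norm of `W` by default,
  consistent with row sparsity; an `abs-sum` mode (Σ_j |w_ij|) is
  provided as an alternative reading of "sum per feature".  Ties break
  by ascending feature index for reproducibility.

## Feature scaling

Rankings based on row norms of `W` are only meaningful when features
share a scale: a feature measured in larger units gets a smaller
coefficient for the same explanatory power.  The package therefore
ships `scale_features` (divide each feature by its SD, **no centering**)
and the recovery experiments use it.  Centering is deliberately avoided:
the regression has no intercept term, so removing feature means strips
exactly the mean structure the model can otherwise exploit to fit the
label offsets — empirically, centering sharply degrades support
recovery while unit-SD scaling improves it.  Raw (unscaled) input
remains the default fit path, appropriate when features already share a
physical scale, as raw EEG amplitude samples do.  The optional
`standardize` flag (full z-scoring) is retained for API completeness
but is not recommended for intercept-free fits.

## Synthetic data

`make_sparse_classification` plants `n_informative` discriminative
features among `n_features`: each informative feature is elevated by
`effect_size·noise_sd` in exactly one class (assigned round-robin) and
carries independent Gaussian noise; nuisance features are zero-mean with
pairwise equicorrelation `correlation` induced by a shared per-sample
latent factor, exercising selectors under correlated irrelevant inputs.
Defaults (200 samples, 100 features, 10 informative, 3 classes, effect
1.5, noise SD 1, correlation 0.2) give a regime where the planted
support is statistically recoverable but not trivial.  A Monte-Carlo
test confirms the realized class-mean separation matches `effect_size`
within 20%.

`make_surrogate_eeg` emits corpora in the Bonn ASCII dialect: one
directory per group (A–E; the Z/O/N/F/S mirror names are accepted on
load), one file per segment, one integer amplitude per line, 4097 lines
by default.  Segments are stationary AR(2) processes with class-specific
coefficients and amplitude scales (the ictal-like group E is strongly
resonant and large-amplitude).  This reproduces the *format* and a
class-separable structure, not EEG physiology: no artifacts, no seizure
morphology, no channel montages.  Tests passing on these surrogates
validate the pipeline mechanics and format handling, not clinical
performance.

## Evaluation protocol

Repeated stratified holdout (default 75/25, 100 repeats; the test suite
and examples run 5–20 repeats to keep desk-scale runtimes in seconds),
top-k grids of 5…100 step 5, 5-fold CV hyperparameter tuning on the
training side only, and a θ × m scan (θ over
{0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 1.5, 2, 2.5}, m over 1…10) at a
fixed k = 55.  Feature rankings are recomputed inside each repeat on the
training part, so no test information reaches the selector; an
instrumented-ranker test asserts this.  A "rank-once" mode (pass a fixed
ranking) exists for literal-protocol comparison.  Per-class train counts
are rounded per class and reconciled to within one sample of the global
75% target.

Classifier adapters: ridge regression on one-hot targets (closed form,
centered, argmax decision; penalty CV-tuned over a log grid
1e-3…1e2) is the native reference adapter; the Gaussian-kernel SVM
delegates to scikit-learn with CV over C ∈ {0.1, 1, 10, 100} and
γ ∈ {scale, 0.001, 0.01, 0.1}.  The CV grids are package choices — the
protocol prescribes tuning, not the grids.  A majority-class adapter
provides the chance-level control.

## Known limitations

- IRLS convergence is linear; very tight tolerances on large problems
  can hit `max_iter` without the `converged` flag (the returned iterate
  is still feasible and its objective monotone).
- The selector is linear: class structure expressed purely in feature
  variance (as in zero-mean stationary signals) is invisible to the
  ranking unless a nonlinear readout or feature extraction precedes it.
- Support-recovery figures quoted in the tests are properties of the
  synthetic generator's regime; they do not transfer to arbitrary real
  datasets.
- The baselines of the original benchmark family (mutual-information
  filters, recursive elimination wrappers, relief-style filters) are not
  implemented; the harness accepts any externally produced ranking for
  comparison.
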