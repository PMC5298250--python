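# Methods

## Model

The package estimates task-optimal linear encoders. A training set of N
contrast-normalized stimuli (each row mean-subtracted and scaled to unit
Euclidean norm) is partitioned into N_lvl discrete latent-variable levels;
the per-level counts define the prior p(Xᵢ) = Nᵢ/N and each stimulus is
equiprobable within its level (p(sᵢⱼ|Xᵢ) = 1/Nᵢ). A bank of q unit-norm
filters responds to a stimulus with mean r = fᵀs and additive Gaussian
noise of variance σ² = α·|r| + σ₀², independent across filters. The scaled
additive form (α > 0) is a standard simple model of cortical response
variability; α = 0 recovers constant additive noise. The Gaussian is taken
literally: responses are signed and unclipped, so contrast reversal of a
filter (f → −f) negates every mean response, leaves every variance
unchanged, and therefore leaves the cost exactly invariant — the origin of
the 180° symmetry of the rotation landscapes.

Because stimuli and filters are both unit norm, mean responses lie in
[−1, 1] and the response units are abstract "spk/s-like" units matching the
default σ₀² = 0.23; no physical calibration is attempted.

The posterior over levels given a response R is the within-level likelihood
sum divided by the total likelihood sum. All likelihood arithmetic is done
in log space with log-sum-exp reductions (with thousands of exemplars the
raw Gaussian densities underflow); the posterior decomposition object keeps
log Y and log Z and exponentiates only for the normalized posterior. The
expected cost of an estimate is computed exactly from the posterior, not by
sampling. Two cost functions are implemented: the 0-1/KL cost (negative log
posterior at the correct level; optimal estimator MAP, ties broken toward
the lowest level index for determinism) and squared error (optimal
estimator the posterior mean). The raw 0-1 expected cost (MAP error rate)
is exposed as a diagnostic but learning uses the KL form.

By default the per-stimulus expected cost is evaluated at the noiseless
mean response rather than averaged over noisy response draws. Filter
learning uses this approximation throughout; a Monte-Carlo mode is retained
for verification, and the two agree increasingly well as the noise power is
scaled down (tested).

## Gradients

The analytic gradients of both costs reduce to gradients of pairwise
Gaussian likelihoods p(r(k,l) | sᵢⱼ). Each likelihood depends on a filter
through the observed mean response (∂r_kl/∂f = s_kl), the candidate mean
response (∂r_ij/∂f = s_ij), and — because the noise is scaled additive —
the candidate variance (∂σ²/∂f = α·sign(r_ij)·s_ij). All three terms are
included; at r = 0 the subgradient of |r| is taken as 0 (a measure-zero
event that keeps the gradient finite). The binding correctness contract is
equivalence with central finite differences of the implemented cost, which
holds to ~1e-6 relative error at step 1e-6 across random instances for both
costs and for α = 0 (where the variance term vanishes). The implementation
is an O(N²) vectorized pairwise accumulation per filter; it is used at
mini-batch scale, so it is deliberately unchunked.

## Optimization

Filters live on the unit hypersphere, so each Euclidean gradient is
projected onto the tangent plane at the filter (applied twice to cancel
rounding), a unit-length step of size ε is taken along the negative
projected gradient, and the filter is renormalized. Renormalization is the
simplest retraction — the projected step leaves the sphere only at O(ε²) —
and keeps the unit-norm invariant exact; whether an exact geodesic
retraction would behave differently was left open, and renormalization was
chosen for simplicity.

Mini-batches are stratified: a fixed number of stimuli per latent level,
drawn without replacement, with the batches of one pass partitioning each
level's shuffled stimuli as closely as the batch size allows. Stratification
is used because batch sizes are naturally reported per level and it
guarantees every level is represented (an empty level makes the posterior
undefined). A step is accepted only if the same batch's cost decreased —
random batches differ in difficulty, so an unconditional step could be
fooled by an easy batch. The step size decays 1% per iteration from a
default ε₀ = 0.05 (a tunable; there is no principled initial value) and the
loop stops after a fixed iteration budget (default 300); an optional
tangent-gradient-norm early stop exists but is off by default. The cost is
non-convex, so multiple random restarts (independent standard-normal
initial filters, normalized) are supported and the restart with the lowest
final full-set cost is kept. All q filters are optimized jointly by
default; a sequential mode (learn a pair, freeze it, add the next) is
provided. With the batch equal to the full set the identical loop performs
deterministic full-batch descent, and the code path reduces exactly (same
iterates) in that case.

Complexity is instrumented by a counter that adds one operation per
(observed response, candidate stimulus, level) triple in every posterior
evaluation: a full evaluation costs N²·N_lvl operations and one SGD pass
costs N_bch·N_lvl·N. The posterior/cost path processes observed stimuli in
blocks of 1024, so the 10,000-stimulus, 20-level full evaluation
(2×10⁹ operations) runs comfortably in memory.

## Synthetic energy task

The generator emulates estimation problems — disparity, speed, and other
"energy-model" tasks — in which the latent variable is carried by the
covariance of quadrature filter-pair responses rather than by response
means. Each stimulus is two concatenated half-windows of d/2 samples: the
first a Hann-windowed sinusoid (default 2 cycles per half-window) with
phase uniform on [0, 2π) and amplitude log-uniform over one decade
(10^−0.5–10^0.5; the amplitude law after normalization is a free choice and
this default is documented as such), the second the same sinusoid with
phase advanced by shift_gain·Xᵢ, plus i.i.d. Gaussian pixel noise
(sd 0.2) in both halves, then mean-subtracted and unit-normalized. The
default shift_gain = 0.08 rad/latent-unit keeps the extreme levels of the
default ±15 range inside (−π, π) so every level has a distinct relative
phase. Defaults follow the reference disparity-style configuration
(19 levels spanning ±15 task units, 400 stimuli per level, 7600 total).
With shift_gain = 0 the level-conditioned stimulus distributions are
identical, and increasing the gain monotonically separates the
level-conditioned response covariances of a fixed quadrature pair (both
tested).

What the generator does not emulate: natural-image statistics (1/f spectra,
broadband orientation content, spatial heterogeneity), optics and
photoreceptor sampling, and multi-frequency carriers. Passing tests
therefore demonstrate the correctness and qualitative behavior of the
method — convergence, batch-size degeneration toward PCA, the
scaled-additive coding advantage, landscape symmetries — on a task with the
right information structure, not quantitative filter shapes for natural
stimuli.

Priors are manipulated by randomly culling stimuli per level to counts
proportional to target weights at the largest feasible scaling (round to
nearest, at least one stimulus per level with positive weight). Levels
given zero weight are dropped and labels re-indexed, because the decoder
requires every represented level to be non-empty. Culling removes rows
only; surviving stimulus vectors are bit-identical.

The PCA baseline is the top-q principal components of the stimuli
(labels ignored), computed with scikit-learn, unit norm, ordered by
eigenvalue, sign fixed by making each component's largest-magnitude element
positive, with an explicit rank check.

## Subspace analyses

A filter pair is expressed in an orthonormal basis of its span with the
first basis vector along f₁, so rotation angle θ = 0 is the input pair.
Pairs are parameterized by (θ, δ) with cosine similarity ρ = cos δ;
Gram–Schmidt orthogonalization keeps f₁ and orthonormalizes f₂ within the
span. Noise-model comparisons match noise power by setting the constant
additive variance to the mean of the scaled model's variances over all
(stimulus, filter) entries. Landscape grids default to θ in 5° steps over
[0°, 360°) and δ in 5° steps over (0°, 180°), resolving the 90°/180°
symmetries at desk scale. Uncertainty ellipses map the diagonal response
covariance into subspace coordinates via B⁻ᵀ; the basis-change matrix is
inverted only when |ρ| ≤ 0.999 (conditioning guard).

## Numerical choices and problem sizes

- Tolerances: unit-norm invariants 1e-10; tangent orthogonality 1e-12
  (enforced inside the training loop, recorded in the trace); posterior
  normalization 1e-12; landscape symmetries hold to ~1e-15 and are tested
  at 1e-8.
- Degenerate inputs: zero-contrast stimuli are rejected (or regenerated
  inside the generator, with a cap that surfaces recurring degeneracy);
  collinear filter pairs are rejected for subspace construction; the L2
  cost requires numeric level values.
- Test and acceptance problem sizes — chosen as representative desk-scale
  instances of the study conditions: convergence studies use 5 levels ×
  100 stimuli at d = 16 with q = 2 over 3 seeds (full-batch 200
  iterations, SGD 300); symmetry suites use 5 levels × 50 stimuli; the
  gradient oracle uses 20 random instances with d ≤ 32, ≤ 5 levels and
  ≤ 10 stimuli per level; the complexity check runs a real 10,000-stimulus,
  20-level evaluation.

## Known limitations

- Correlated (non-diagonal) response noise, Poisson/Bernoulli likelihoods,
  and half-rectified responses are out of scope.
- Gradients are derived under the noiseless-mean-response approximation of
  the cost; gradients of the Monte-Carlo cost are not implemented.
- The L2 landscape can be flat in directions the posterior mean is
  insensitive to; learning under L2 is supported but the KL cost is the
  default and the better-behaved objective at these problem sizes.
- The cost is non-convex; restarts mitigate but do not eliminate local
  minima.
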