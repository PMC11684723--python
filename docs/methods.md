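# Methods

This note documents the models and algorithms implemented in `mppvae`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Problem setting

Unsorted ("clusterless") extracellular recordings are event streams
{(t_i, κ_i)}: spike times with attached mark vectors κ (here, waveform
snippets), used directly without spike sorting.  Under a marked
inhomogeneous Poisson assumption driven by a state x_t, the process is
characterized by the joint mark intensity λ(x, κ): λ(x, κ)Δt is the
expected number of events with mark κ in an interval of length Δt at
state x.  With events on (0, T] and the state measured on a grid
t_j = jΔt, the discretized log-likelihood is

    Σ_i log λ(x_i, κ_i) − Σ_j λ(x_j) Δt,

with λ(x) = ∫ λ(x, κ) dκ the ground intensity and x_i obtained by
nearest-neighbor interpolation of the grid states.  The bin width Δt is
kept explicit internally; a flag can absorb it into the base rate
(which only shifts log λ₀ by log Δt).

## Joint mark intensity VAE

The intensity is decomposed as λ(x, κ) = λ₀ ∫ p(x, κ | z) p(z) dz with a
low-dimensional latent z, p(z) = N(0, I), and p(x, κ | z) =
p(x|z) p(κ|z) a product of Gaussian networks (x and κ conditionally
independent given z).  The factorization makes the ground intensity's
density ∫ p(x,κ|z) dκ = p(x|z) directly available.  Two encoders,
q(z|x,κ) and q(z|x), act as importance proposals.

All Gaussian networks are MLPs (default 2 hidden layers × 64 tanh units)
emitting a mean and a **diagonal** precision through softplus with a
floor of 1e-4 — positive definite for every input by construction.  The
architecture width/depth and latent dimension are free hyperparameters;
the defaults were chosen once as a small architecture adequate for the
synthetic benchmark (d_z = 4 for 32-sample waveform marks).

The x-decoder's precision is additionally soft-capped (tanh saturation,
default 100, i.e. a per-dimension sd floor of 0.1).  When the hidden
dimension exceeds the data's intrinsic dimensionality the unused state
directions collapse, and an uncapped decoder makes the intensity decay
off that thin manifold arbitrarily fast — which later lets silent bins
repel the MAP decode toward zero-intensity regions.  The cap bounds
that decay rate; it is a regularization choice of this implementation.

Because the networks are tanh MLPs, covariates should be O(1): the
experiment pipeline z-scores y with training statistics (and reports
decoding errors in original units).

## Evidence bounds

Each spike contributes a log-evidence term bounded below via the
α-divergence (Rényi) bound,

    log p(x,κ) ≥ (1/α) log E_q[(λ₀ p(x,κ|z)p(z)/q(z|x,κ))^α],

and each grid point contributes a *negative* evidence term −λ₀ p(x_j),
bounded via the χ-divergence upper bound

    p(x) ≤ (E_q[(p(x|z)p(z)/q(z|x))^β])^{1/β},

whose minimization is consistent with maximizing the overall objective.
Both are estimated with L Monte-Carlo samples through the
reparameterization trick, always in the log domain with log-sum-exp
(finite for log-weights anywhere in [−700, 700]).

Defaults: α = 0.5, β = 2, L = 10.  α is restricted to (0, 1] (α = 1 is
the tightest, the importance-weighted bound; α → 0 recovers the
KL/ELBO); β = 2 additionally minimizes the variance of the evidence
estimate at the optimal encoder.  The concrete values are defaults
inside the admissible ranges; they are deliberately configurable.

Finite-sample behavior worth knowing: the plug-in χ estimator
T_L = ((1/L)Σ w^β)^{1/β} is *unbiased for p(x) at L = 1* and converges
to the (larger) χ-bound value as L → ∞; its finite-L bias relative to
that limit is what breaks the lower-bound guarantee of the combined
objective.  Jackknife (leave-one-out) correction removes the O(1/L)
bias at the cost of variance and is applied to the χ term by default
(the Rényi term has its own flag, off by default, since its bias does
not break the bound direction).  Doubly reparameterized gradients are
implemented for the α = 1 spike terms: the encoder gradient is replaced
by the w̃² -weighted path derivative, which removes the high-variance
score component.  The χ term is exponentiated from a log-domain value
clamped at 50 to prevent overflow early in training; clamp events are
logged.

All-zero-weight batches yield −inf spike terms (treated as a diverged
step by training) and zero χ terms, rather than raising.

A practical consequence of training against the χ *upper* bound of the
intensity integral: while q(z|x) is loose, the integral term is
overestimated and the fitted intensity shrinks below the true rate to
compensate (the estimated integral, not the true one, matches the spike
count at the optimum).  The fit is therefore conservative early in
training and tightens as the state encoder improves; decoding is
affected only mildly because a near-uniform shrinkage is absorbed by
the base rate.

## State-space model

When the covariate y is itself an observation, a hidden state x_r on R
equal bins follows linear-Gaussian dynamics

    x_1 ~ N(a₁, V₁⁻¹),  x_r | x_{r−1} ~ N(F x_{r−1} + a, V⁻¹),

with a Gaussian-network observation p(y_r|x_r) and the marked point
process (through the VAE intensity) as the observation model for the
per-bin mark sets κ_r.  Bins may be empty.  The hidden dimension
defaults to 10.

The variational posterior is structured: chain factors q(x₁),
q(x_r|x_{r−1}) (their own parameters b₁, W₁, G, b, W) times per-bin
Gaussian experts — one from y_r, one per spike mark (a network applied
to each κ_ri, precisions summed), and one constant "base" expert that
stands in for the exp(−λ(x_r)) factor.  The product is Gaussian with a
block-tridiagonal precision; assembly is in information form and the
mean solves the assembled information vector.

The ELBO E_q[log p(x) + log p(y|x) + Σ_r L_r(x_r) − log q(x)] uses the
per-bin Rényi/χ bound L_r for the point-process term; log q of sampled
paths is evaluated exactly from the block factorization (the quadratic
form of a reparameterized draw is ε'ε by construction, so the entropy
term is deterministic given the noise).

Training maximizes the ELBO over all parameters simultaneously with
Adam, one Monte-Carlo path sample per step, early stopping on a
held-out validation segment.  Long recordings are batched into
contiguous segments (default 200 bins) with a 1-bin overlap; a
non-initial segment reuses the initial-distribution factor at its first
bin.  This segmenting is our choice — the chain factors couple
neighbors, so fully random minibatching is not available.  F and G are
initialized to 0.99 I (slow near-identity dynamics, a standard stable
initialization), V, W to I, offsets to 0.  Non-positive-definite
assemblies receive 1e-6 I jitter up to three times (logged) before
failing; −inf objectives abort with diagnostics.

The observation precision Λ(x_r) is state-dependent diagonal (the same
network head as the mean), matching the general form rather than a
constant matrix.

## Block-tridiagonal linear algebra

Factorization is a block Cholesky forward recursion (R diagonal and
R−1 subdiagonal blocks); solves, log-determinants, and sampling
(u = L⁻ᵀ ε) reuse the factor, all at cost linear in R.  No dense
(Rd)×(Rd) matrix is formed on these paths.  Diagonal blocks are
symmetrized on input with a warning above 1e-8 asymmetry; a failed
factorization reports the failing block index.

Because training differentiates through posterior sampling, the block
recursion is written on top of a small reverse-mode autodiff engine
(`mppvae.autodiff`) whose primitives include the dense d×d Cholesky and
triangular solves with their standard adjoints; gradient correctness is
established against central finite differences in the test suite.

## Decoding

Decoding reconstructs y from spikes alone: the state posterior
p(x|κ) ∝ p(x) Π_r p(κ_r|x_r) is approximated by Laplace — a Gaussian at
the MAP path with precision equal to the negative Hessian there — and
the covariate posterior follows by decoder averaging over S posterior
samples, p(y|κ) ≈ (1/S) Σ_s p(y|x_s), with a law-of-total-variance
(diagonal) uncertainty.

The per-bin bound L_r is not concave in x_r, so each Newton iteration
concavifies it by the Gauss-Newton composite technique: the spike term
is written as π(F(x)) with inner values F_l = w_l^α > 0 and outer
π(v) = (1/α) log mean(v) (concave increasing), the χ term as ρ(G(x))
with inner log-weights and outer ρ(v) = −(mean e^{βv})^{1/β} (minus the
exponential of a convex log-sum-exp).  Linearizing the inner maps at
the expansion point makes both composites globally concave, so the
Newton system (prior block-tridiagonal precision plus per-bin negative
Hessians) is positive definite and every step is an ascent direction.
At the expansion point the surrogate matches the unapproximated bound
in value and gradient exactly.

Latent samples inside F and G are drawn from the trained encoders at
the current iterate and frozen within the iteration; they are redrawn
at each re-expansion through a fixed base-noise stream (common random
numbers), which makes the iteration map deterministic and the objective
trace stable.  Because the state enters the frozen weights only through
the decoder's Gaussian quadratic, the exact frozen-sample objective is
available analytically at any point; backtracking (≤ 10 step halvings)
accepts a step only if that re-expanded objective does not decrease,
guarding the Monte-Carlo re-linearization noise.  Convergence is
declared when the Newton step's infinity norm falls below 1e-6 (or no
ascent is possible at line-search resolution); K_max = 50, L_dec = 32
samples per term.  Initialization is the prior mean path (a₁ propagated
through F).  The alternative recursive filtering formulation is not
implemented; direct optimization is the single decoding path.

The printed composite forms hold the encoder arguments at the expansion
point x̄; we refresh them at every re-expansion, which recovers the same
fixed point while letting the proposals track the iterate.

## Synthetic generator

The hidden state is a Lorenz attractor (σ = 10, ρ = 28, γ = 8/3),
integrated by fixed-step RK4 (dt 1e-3, subsampled to the covariate
grid); the covariate is the full state (Lorenz_3D) or the [x₁, x₃]
projection (Lorenz_2D).  Spikes come from a mixture intensity

    Σ_l λ_l exp((t/T · c_l + (1 − t/T) · d_l)ᵀ x_t) · ∫ N(κ|μ(z), Λ(z)) N(z|μ_l, Λ_l) dz,

whose tuning direction drifts linearly over the trial (a plasticity
surrogate).  As printed, the c_l vectors receive the t/T weight (so the
direction is d_l at t = 0 and c_l at t = T) even though c_l is described
as the t = 0 direction; the formula as printed is implemented and a
`swap_cd` flag exposes the other reading.

Unpublished generator constants were fixed once at realistic values:
Lorenz coordinates are O(10–20), so tuning directions are unit vectors
scaled to 0.08 (per-component rate modulation about e^{±1.6}) and
λ_l = 4 /s, giving ~15–30 spikes/s per probe over four components —
comparable to a moderately active tetrode channel.  The waveform
decoder is a synthetic affine map from a 2-D latent to 32 samples per
site: a sharp negative template with a slow rebound plus bump-shaped
loading columns and diagonal noise (sd 0.2).  Defaults: 4 probes × 4
components, T = 100, Δt = 0.01; the validation studies in this package
run a scaled-down T = 20, 1-probe version (problem sizes chosen as the
package's standard small benchmark).

Simulation is exact Ogata thinning against per-window majorants (grid
maximum × 1.2, inflated and replayed on the rare violation).  The
ground-truth intensity along a sampled path is defined piecewise
constant in time (nearest-neighbor state), so the time-rescaling
theorem applies exactly: transformed inter-event intervals are Exp(1),
which the tests verify by KS.  A per-bin Bernoulli approximation is
deliberately not used for generation (it discretizes the law).

What the generator does *not* emulate: refractoriness or any history
dependence, spike collisions across sites, probe drift,
non-Gaussian waveform noise, and real waveform statistics.  Passing
the benchmark therefore demonstrates correctness of the estimation and
decoding machinery under the model's own assumptions, not robustness to
real-recording artifacts.

## GMM baseline and comparisons

The baseline intensity is Σ_l λ_l N(x|μ_l^x, Λ_l^x) N(κ|μ_l^κ, Λ_l^κ)
with diagonal precisions; its ground intensity is the exact κ-marginal,
so its likelihood is exact (the reference objective — bound-based NLLs
of the VAE model are upper bounds, a disadvantage the comparison
inherits).  Fitting is Adam ascent on the exact objective over
log-scales, means, and log-precisions (KMeans on marks seeds the
components; precisions are capped at 1e4 against collapse).  The
mixture is non-concave in x, so GMM decoding reuses the same
Gauss-Newton concavification with the components playing the role of
the frozen samples; the chain prior over the covariate space is an
AR(1) fitted by least squares.  Default 16 components.

Model comparison: per-trial (or per-fold) paired scores, Wilcoxon
signed-rank per model pair (scipy), Holm-Sidak step-down adjustment
(statsmodels; the step-down formula is independently verified in the
tests), significance at adjusted p < 0.05.

## Numerical and edge-case policy

* float64 throughout; marks may be float32 on disk, promoted on load.
* Bins are left-open/right-closed, matching the (0, T] convention;
  nearest-neighbor midpoint ties go to the later grid point; duplicate
  spike times are allowed and preserved in input order.
* Degenerate Jacobians in the concavified terms reduce to constant
  bounds with zero curvature.
* Seeds: every stochastic routine takes an explicit seed; one shared
  seed stream per training step.

## Known limitations

* Intensity values are Monte-Carlo estimates; there is no deterministic
  evaluation path for λ(x, κ).
* Diagonal precisions everywhere (networks and experts): correlated
  observation noise must be whitened upstream.
* The structural constraint q(z|x) = ∫ q(z|x,κ) p(κ) dκ between the two
  encoders is not enforced (separate networks).
* The CPU-bound autodiff engine limits practical problem sizes to the
  scaled benchmark regime (thousands of bins, tens of thousands of
  parameters); real 200k-spike recordings would need a GPU-backed
  tensor library behind the same interfaces.
* Training is non-convex: the end-to-end benchmark fixes seeds and
  treats "beats the constant-mean predictor after training" as its
  learning criterion, not recovery of the generator's parameters.
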