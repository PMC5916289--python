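# Methods

## Model

`rnevolve` simulates the evolution of population mean traits for organisms
with plastic phenotypes, in discrete non-overlapping generations. Three
ingredients define the model.

**Individual reaction norms.** Each individual carries a trait vector
partitioned into elevations `z_a` (m phenotypes), slope/shape coefficients
`z_b`, and reference traits `z_c` (one per environmental cue, q cues). The
phenotype expressed at cue vector `u` is

    y = z_a + Z_b ũ + e,

where `ũ` is a vector of p monomials ("cue products") in the shifted cues
`u − z_c` — e.g. `(u1−c1)`, `(u1−c1)²`, `(u1−c1)(u2−c2)` — declared by a
`ReactionNormSpec` as exponent vectors, with a boolean mask selecting which
slope coefficients structurally exist. `e` is a non-additive residual,
independent of the traits, with covariance `resid_cov` (σe² on the
diagonal). The flat trait layout is `(z_a | active z_b column-major | z_c)`;
this fixes an unambiguous indexing for all covariance blocks (Gaa, Gbb, Gcc
and the cross blocks).

The reference traits are the novel state variables: they locate the norm
along the cue axis, and with additive genetic variance (`G_cc` positive
definite) they evolve. A plausible biological mechanism is variation in how
individuals *perceive* the environment, which shifts each individual's norm
horizontally.

**Gaussian stabilizing selection.** Individual fitness is
`W = W_max · exp(−D/2ω²)`, where the mismatch `D` is either the sum of
squared deviations `Σ_j (y_j − θ_j)²` (package default, the standard
multivariate form) or the squared summed deviation `(Σ_j (y_j − θ_j))²`
(a single selective dimension). An optional cost of plasticity multiplies in
`exp(−Σ_k cost_k z_b,k²/2ω²)`; the zero-cost path is bit-identical to the
cost-free form. The bundled bivariate step-response experiment (`fig2`
preset) uses the squared-sum form: with the sum-of-squares alternative the
second reference trait does not finish assimilating within that experiment's
10,000-generation protocol, while under the squared-sum form the documented
outcome (complete assimilation, only b̄11 nonzero at stationarity) is
reproduced. For univariate phenotypes the two forms coincide, so all other
presets are unaffected.

**Environment.** Each generation draws one joint multinormal vector of cues
and optimum `(u_t, θ_t)` with constant covariance and means that may change
in scheduled steps; draws are independent across generations (white
process). Development and selection use the same draw — no within-generation
lag. The covariance `cov(u, θ)` is what makes plasticity adaptive: it
determines the stationary mean slopes. For the two-cue experiments the
optimum is constructed from latent "selection environments",
`θ = B(ε_1s + ε_2s)` with cues `u_i = ε_id`, giving `μ_θ = B(μ_U1 + μ_U2)`.

**State equation.** The mean trait vector follows the augmented multivariate
breeder's equation

    z̄(t+1) = z̄(t) + G_aug β(t),   β(t) = P_aug⁻¹ cov(W_i, z_i) / W̄,

with `G_aug` (additive genetic) and `P_aug` (phenotypic trait) covariances
held constant — only means evolve; G/P evolution is out of scope. At
stationarity the expected gradient E[β] = 0, and for symmetric phenotype
distributions the expected means satisfy E[z̄_a] = μ_Θ and E[z̄_c] = μ_U.
Zero rows/columns of `P_aug` (pinned traits, e.g. `G_cc = 0`) are excluded
from the inverted subspace; their gradient is zero and, when the matching
`G_aug` rows are zero, their means are *exactly* constant — the undriven
integrator that classic fixed-reference models implicitly assume.

The non-additive component of the elevation trait (z_a = a + e in the linear
examples) is represented as the phenotype-level residual `e` with `P_aug =
G_aug`; because the elevation enters the phenotype additively, this is
equivalent in the mean dynamics to placing σe² inside `P_aug` (verified
against the quadrature oracle), and it keeps the trait covariances and the
residual cleanly separated.

## Estimator

`cov(W, z)` and `W̄` are estimated per generation from `n` individuals
sampled from N(z̄, P_aug) (plus independent residuals): the unbiased sample
covariance and the sample mean over the same individuals. This is the
natural Monte-Carlo analogue of the population-level identity; a
deterministic tensor Gauss–Hermite oracle for the univariate linear model
(in the test suite) confirms the estimated one-step mean change to within
Monte-Carlo error, with error decaying as n^(−1/2).

Sampling uses an eigenvalue-clipped PSD factor of `P_aug`, computed once per
run (covariances are constant), so boundary states with pinned traits sample
exactly on the support of their distribution. PSD validation uses a relative
eigenvalue tolerance of 1e−10 times the largest diagonal entry, keeping
float-perturbed boundary cases valid.

**Seeding.** One master seed per run; each generation derives two child
streams (environment, individuals) from `SeedSequence(seed, spawn_key)`.
Runs are bit-reproducible, and the realized environment sequence is
identical across runs that differ only in `n` — so population-size
comparisons see the same environments.

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| `omega_sq` (ω²) | squared phenotype | 10 (presets) | width of stabilizing selection; weak selection regime of the reference experiments |
| `G_aug` diagonal | squared trait | preset-specific (0.5 elevations/references, 0.04–0.045 slopes) | reference experiment values |
| `resid_cov` (σe²) | squared phenotype | 0.5 | reference experiment value |
| `n_individuals` | — | 10,000 (fig1), 5,000 (fig2/fig4) | selection-differential noise small relative to G entries at desk scale; fig2/fig4 use their documented protocol size |
| `n_generations` | generations | 2,000 (fig1), 10,000 (fig2/fig4) | documented protocols |
| environment covariances | mixed | preset-specific | printed values where available; see provenance notes |

Preset fields carry provenance flags: `"reference"` for values taken from
the documented experiments, `"default"` for values those experiments do not
print. Two blocks are defaults of this package: (i) the two-cue experiment's
environment process (μ_U = (1,1), B = 1, var(ε) = 0.5, correlation 0.5
between cue indices and 0.8 between developmental and selection stage,
cross-correlations from the Kronecker product structure, which guarantees a
PSD covariance and produces correlated cues with cue–optimum covariance);
(ii) the fig1 presets' fitness/θ process (borrowed from the bivariate
experiment's printed values, with μ_Θ = μ_U·b̄) used only for the
"reference evolves toward the new mean cue" demonstration.

## What the simulations show — and what they do not

The synthetic experiments emulate idealized infinitesimal-model populations:
multinormal trait distributions with constant G and P, no drift (sampling
noise is an estimator artifact, not finite-population drift), no mutation,
no autocorrelated environments, no within-generation environmental change,
and no biological constraints on how far reference traits can move. Passing
tests therefore demonstrate properties of this model class, not of real
populations: real G matrices evolve, environments are autocorrelated, and
assimilation to arbitrary environments is limited by physiological
constraints and plasticity costs.

Two estimator-level caveats matter when interpreting trajectories. First,
weakly selected slope combinations (the quadratic/interaction terms of the
bivariate experiment) have restoring forces that are second order in cue
fluctuations; their window means wander at the few-percent scale over
thousands of generations, driven by the realized environment sequence, at
any population size. Second, under the squared-sum fitness form only the sum
b12 + b22 of the two curvature coefficients enters the selected phenotype;
the difference is exactly neutral and random-walks under estimator noise.
Statements about "slopes returning to zero" concern the selectively
constrained combinations.

## Numerical choices

* Gradient solve: Cholesky factorization of the positive-variance block of
  `P_aug`, computed once per run; a singular active block raises an error
  directing the user to drop zero-variance or collinear traits.
* Variance-minimum search (`empirical_variance_curve`): one common sample of
  individuals is reused across the whole cue grid (common random numbers),
  removing between-point jitter; the argmin is refined by a parabola through
  the three points around the discrete minimum.
* Batch-means standard errors (`equilibrium_summary`): the window is split
  into contiguous batches (default 20; use fewer, longer batches for
  slow-mixing traits such as references, whose autocorrelation time is
  hundreds of generations). A window of length 1 yields NaN errors with a
  warning.
* Degenerate inputs: zero covariance matrices are valid (deterministic
  populations/environments); every cue product must have total degree ≥ 1,
  so `u = z_c` zeroes the plastic term exactly; non-finite means abort the
  simulation with a diagnostic.
* Assimilation flag: slope deltas < 0.05 trait units and fitness delta
  within 2 combined batch-means standard errors, plus (optionally) reference
  deltas matching the applied cue step within 0.3 — the Monte-Carlo noise
  floor at the default population sizes.

## Design notes

* The reference traits default to fully additive (`E_cc = 0`), matching the
  worked examples; a non-additive reference component can be expressed
  through `P_aug > G_aug` if needed.
* Plasticity cost defaults to zero: the documented two-cue experiment found
  its effect negligible, so the cost-free configuration is the reference.
* The classic fixed-reference (two-trait / two-cue) models are recovered
  exactly as the `G_cc = 0` special case; the test suite cross-checks this
  against an independently coded classic simulator and a quadrature oracle
  configured without the reference trait.
* Experiment presets default to the documented protocol sizes; the fig1
  presets use 10,000 individuals (default for new configurations), fig2 and
  fig4 their documented 5,000.

## Known limitations

* Function-valued (index-environment) reaction norms are not implemented;
  the model is parametric (polynomial in shifted cues).
* Identification of `G_cc` from dynamical experiments is out of scope.
* Environmental autocorrelation and spatial structure are not modeled.
* `G` and `P` are constant; evolvable covariance matrices are not supported.
* The closed-form variance-minimum formula is exact for the stated case
  `G_ab = G_bc = 0`; elsewhere the empirical curve is authoritative and
  discrepancies are reported, not asserted.
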