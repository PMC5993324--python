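# Methods

`gpcuq` implements a surrogate-model pipeline for global sensitivity
analysis and Bayesian parameter estimation of expensive dynamical models,
demonstrated end-to-end on two models of the budding-yeast pheromone
response: an ODE model of the heterotrimeric G-protein cycle and a
reaction–diffusion model of Cdc42 polarization on a circular membrane.
This note records the models, the numerical choices, and the design
decisions that were genuinely open.

## Parameter spaces and the reference cube

Every parameter is assumed independent and uniformly distributed over a
stated range, either in natural units (`linear`) or in `log10` of them
(`log10`); each is mapped affinely onto the reference interval [−1, 1].
All downstream machinery — surrogate fitting, sensitivities, the MCMC
prior — lives on the cube [−1, 1]^n with the uniform product measure, and
converts to natural units only at the model boundary. Log mapping uses
base 10 because ranges are quoted in decades (e.g. kGa ∈ [10⁻⁷, 10⁻³]);
any fixed base is equivalent up to the affine rescale.

Four spaces ship with the package: the two-parameter G-protein space
(kGa, kGd, both log), an eight-parameter space spanning two decades
geometrically centred on the baseline rates (a reconstruction — the
original ranges were published only in supplementary material), and the
35- and screened 15-parameter polarization spaces (Hill exponents q, h on
a linear scale, everything else log).

## Model 1: the G-protein cycle

Four ODE species — receptor R, ligand-bound receptor RL, heterotrimeric
G-protein G, and active Gα (Ga) — with the inactive Gα pool and free Gβγ
algebraic: Gd = Gt − G − Ga, Gbg = Gt − G. Units are molecules/cell and
seconds; ligand L is in nM. The observable is the free-Gβγ fraction
Gbg/Gt on a 15-point grid: a time course at L = 1000 nM
(T = 10…600 s) and a dose response (L = 1…100 nM) read out at T = 60 s.

Baseline constants (whole-cell units): kRL = 2×10⁻³ nM⁻¹s⁻¹,
kRLm = 10⁻², kRd0 = kRd1 = 4×10⁻⁴, kRs = 4, kG1 = 1, Gt = 10⁴, with
kGa = 10⁻⁵ and kGd = 0.1 as the free pair. The initial condition is the
pre-stimulus steady state R = kRs/kRd0, RL = 0, G = Gt, Ga = 0, so the
response at t = 0 is exactly zero; this is the source model's convention
(the equations themselves do not fix it). Integration uses LSODA at
rtol 10⁻⁸ / atol 10⁻¹⁰; points sharing a ligand dose share one
integration. A noteworthy structural feature inherited from the equal
internalization rates kRd0 = kRd1: the saturating time course is
essentially flat after ~30 s, and the response vector is nearly invariant
along the diagonal {c·kGa, c·kGd} for kGd ≳ 0.1 (differences ≤ 0.065,
concentrated at the earliest time point). Consequences for inference are
discussed below.

## Model 2: membrane polarization

Eleven membrane fields (the six G-protein-cycle species in surface-density
form plus membrane Cdc24, inactive/active Cdc42, membrane Bem1, and active
Cla4) on a circle of radius 2 μm, discretized by N = 400 equally spaced
points; angle α is measured from the negative x-axis. Two cytoplasmic
pools (Cdc24, Bem1) are well mixed and defined at every step by exact
conservation of the totals C24t and B1t. Ligand enters as a shallow linear
gradient L(α) = 10 + 0.1·x(α) nM with x(α) = −2 cos α, so the maximum
(10.2 nM) sits at the +x pole α = π. Initial fields are exactly uniform —
symmetry is broken only by the gradient, never by injected noise.

Nonlocal couplings: Gβγ recruits Cdc24 through a Hill function of the
mean-normalized Gβγ field (exponent q), membrane Bem1 recruits more Cdc24
through a second Hill function (exponent h) scaled by the membrane-mean
Bem1, active Cla4 (driven by mean active Cdc42) degrades membrane Cdc24,
and receptor synthesis is redistributed proportionally to active Cdc42
(`ps` field). Where a normalizing integral vanishes the corresponding
Hill term takes its limiting value 0 (and `ps` ≡ 1); Hill arguments are
clamped below at 10⁻¹² and evaluated in log space so exponents up to
q = 100 cannot overflow.

For the 1-D circular membrane we take SA = 2πr ≈ 12.566 μm (total arc
length) and V = πr² ≈ 12.566 μm² (enclosed area); the membrane mean
∫·ds/SA is then a true average and, at radius 2, SA = V numerically, which
keeps the SA/V-scaled rate entries of the baseline table internally
consistent.

### Time stepping

Space: second-order central differences on the periodic mesh. Time: the
trapezoidal (Crank–Nicolson) rule applied to the *full* right-hand side,

    (I − Δt/2·L) U⁺ − Δt/2·F(U⁺) = (I + Δt/2·L) U + Δt/2·F(U),

solved each step by Newton–Picard iteration on the exact residual. The
approximate inverse applied per iteration factorizes into the exact
circulant diffusion solve (FFT; the periodic stencil is diagonal in
Fourier space) composed with batched per-mesh-point 11×11 solves of
(I − Δt/2·J_local), where J_local is the pointwise reaction Jacobian
including the steep local Hill derivatives. Iteration continues to a
residual of 10⁻¹⁰ relative to the field scale (typically 3–5 iterations).

A fully implicit treatment of the reactions is required, not a
convenience: heterotrimer reassociation (kG1·Gd·Gbg with surface
densities ~800 μm⁻²) has local rates of order 10³ s⁻¹, far beyond the
explicit stability limit at the default Δt = 0.05 s. Because the
nonlinear system is solved to tolerance, the pure-diffusion limit of the
scheme is exactly single-step Crank–Nicolson — a single Fourier mode
decays by (1−λ)/(1+λ) with λ = D·k̃²·Δt/2 and k̃² = 4 sin²(kΔs/2)/Δs²
the discrete stencil symbol — and the scheme's steady states are
Δt-independent (they satisfy L·U + F(U) = 0). During the stiff
polarization transient the steep Hill switches reduce the observed
temporal order below two; convergence under Δt-halving is verified by
test, and the formal second order is verified exactly on the linear
subproblem.

Defaults: Δt = 0.05 s, t_end = 1000 s (the state change over the final
10 s is reported as a steady-state diagnostic and is ~10⁻⁴ relative at
baseline). If the nonlinear solve fails to converge on a step — which
happens at extreme parameter-space corners with sharp transients,
especially at coarse Δt — the step is bisected deterministically (up to
six levels) before the failure is reported. A full-resolution run costs
~2 minutes on one CPU.

### Polarization factor and cutoff response

PF = 1 − 2·Sp/SA, where Sp is the arc length of the smallest contiguous
arc around the field maximum containing half of the field's total amount
(greedy expansion toward the larger neighbour, fractional cells by linear
interpolation). PF is 0 for a uniform field, 0.5 for a half-circle
plateau, and → 1 for a spike; it is invariant to positive scaling and to
rotation. Because PF ignores magnitude, the scalar response used for
surrogate fitting and inference is the cutoff response
z = PF·(a·x)⁵/(1+(a·x)⁵) with x = max C42a and a = 2·SA/C42t, which
suppresses profiles whose active-Cdc42 peak falls below half the uniform
initial Cdc42 concentration (a·x = 1 exactly there; exponent 5 gives a
reasonably sharp cutoff).

## Surrogates

Total-degree multi-index sets |α| ≤ d in graded-lexicographic order
(fixed so serialized coefficient files are reproducible), tensor-product
Legendre basis in the unnormalized convention P_m(1) = 1 (coefficients
are convention-dependent; every quantity asserted in tests is not).
Oversampled systems are fit by rank-revealing least squares;
undersampled systems by basis-pursuit denoising,
min ‖c‖₁ s.t. ‖Ac − b‖₂ ≤ ε, solved by a primal log-barrier
second-order-cone method written for this package (Newton steps on the
epigraph barrier with the standard block elimination; ε ≈ 0 dispatches to
the equality-constrained basis-pursuit LP via HiGHS). The default
constraint radius is ε = 0.05·‖b‖₂ — floored just above the design's
best achievable residual, so the constraint set is never empty on
oversampled designs — config-exposed, since no canonical value exists;
it can be grid-searched by cross-validation. Fit quality is
estimated by k-fold cross-validation (error convention:
surrogate − model). One surrogate is fit per response function (per
observation point, or per scalar PF/z response) rather than adding time
or dose as polynomial variables — the right choice when data are sparse.

## Sensitivities

The global sensitivity of response z to cube coordinate y_j is
S_j = E[∂z/∂y_j] under the uniform measure. For a Legendre expansion this
is exact and free: E factorizes over dimensions, E[P_m] = 0 for m > 0,
and ½∫P_m′ = 1 for odd m, 0 for even m, so S_j is the sum of the
coefficients of pure odd-degree terms in y_j. Working in cube coordinates
removes scale bias between parameters of different magnitude and is what
makes sensitivities comparable across parameters. The absolute first
moment E|∂z/∂y_j| has no closed form and is estimated by seeded Monte
Carlo (10⁴ points) with the surrogate's analytic gradient. Screening
retains parameters with |mean_r S_j| above a threshold (default 0.01);
mean |S_j| over responses is reported alongside, and the two criteria
nearly coincide because sensitivities are sign-consistent across
responses in both demonstration models.

## Inference

Likelihood: independent Gaussians per observation with the dataset's
reported sd — the standard reading of mean ± sd data. For the
polarization model the single datum is the measured polarization factor
(0.87) compared through the cutoff response z, with σ_PF = 0.1 by default
(the measurement's sd is unreported; config-exposed). Prior: uniform on
the cube, i.e. the same distribution the surrogate was built under.

Metropolis–Hastings with isotropic Gaussian random-walk proposals in cube
coordinates; proposals leaving the cube are rejected through the prior
(exactly correct, simpler than reflection). The proposal scale can be
pre-tuned toward 20–40% acceptance on a pilot chain and then frozen.
Chains store post-burn-in samples (optionally thinned); a chain that
accepts nothing for 10⁴ consecutive steps aborts with a diagnostic.
Convergence is checked by running independently seeded chains and
comparing marginals: per-parameter histogram total-variation distance and
the two-sample Kolmogorov–Smirnov statistic, both under a configured
tolerance. Posterior summaries: marginal histograms on the cube (log
parameters thus get log-spaced bins automatically), the marginal mode
from the highest-density bin of a 100-bin histogram (joint mode
estimation in 15 dimensions from 10⁶ samples is ill-posed), the mean
parameter set computed in cube coordinates and mapped back, central 95%
intervals, and the cube-coordinate correlation matrix. Simulated
annealing (geometric cooling, Gaussian moves clipped to the cube,
best-so-far tracking) refines a point estimate such as the posterior
mean; it never returns a point worse than its start.

A structural caveat discovered during validation: the two-parameter
G-protein posterior is a long diagonal ridge, and for kGd ≳ 0.1 the ridge
is nearly flat (the near-invariance noted above). At the synthetic noise
level the marginal mode location along the ridge is therefore weakly
identified, while ratio information (the strong positive kGa–kGd
correlation) is robust. Data with per-point noise at the ~0.02 level pin
the mode; at 0.05 they need not. Recovery tests accordingly use the joint
95% highest-posterior-density region (log-posterior rank check), the
appropriate calibration check for region-shaped posteriors.

## Synthetic data

The generator module makes every stage testable without external data;
all generators are pure functions of (spec, seed).

- G-protein observations: exact model response on the standard 15-point
  grid plus i.i.d. Gaussian noise, clipped to [0, 1], default
  sd 0.05 per point (chosen once to match the visual error-bar scale of
  the published fits; the original per-point sds are not redistributable).
  These synthetic sets emulate the structure of the real dataset, not its
  noise realization — fit metrics computed against them include the full
  synthetic noise floor (~sd² = 2.5×10⁻³) and are not comparable to fit
  metrics against the original data.
- Membrane profiles: von-Mises-shaped fields (the natural unimodal family
  on the circle) with controllable sharpness κ and conserved total; κ = 0
  is uniform (PF = 0) and PF increases monotonically with κ.
- PDE sample sets: uniform cube samples of the cutoff response z, with a
  JSON-lines checkpoint making long sampling campaigns restartable and
  partitionable; failed simulations are flagged (z = NaN), never silently
  dropped.

## Problem sizes used in the shipped tests and acceptance script

The test suite and `scripts/acceptance.py` run the two-parameter
G-protein study at full size (1000 training simulations, degree-10
surrogates, 10⁶-step chains) and the polarization model at one
full-resolution steady-state solve (N = 400, Δt = 0.05, t = 1000 s). The
published full-size PDE surrogate campaigns (5000 samples in 35-D, 6000
in 15-D, each sample a ~full-resolution PDE solve) are replaced, as the
package's own scaled test design, by a 200-sample campaign in the 15-D
space at reduced resolution (N = 64, Δt = 0.25, t_end = 150 s) fitting a
degree-2 surrogate with 12-fold cross-validation — the properties checked
(unbiased CV error, exact ℓ1 recovery of planted sparse coefficient
vectors from undersampled designs) are resolution- and scale-independent.

## Known limitations

- The nonlocal coefficient block of the polarization model (the γ, δ
  normalizations and the Bem1 Hill form) follows the mean-normalization
  reading of the source model; variant readings exist and would change
  quantitative steady states.
- Polarized transport of Cdc42, deforming membranes, 2-D/3-D geometry,
  stochastic simulation, and non-uniform priors (Hermite/Laguerre/Jacobi
  bases) are out of scope.
- Polynomial surrogates cannot represent discontinuous parameter
  dependence; the polarization model is known to be multistable in parts
  of its parameter space, which bounds the achievable surrogate accuracy
  regardless of degree or sample count.
- The ℓ1 solver uses dense linear algebra; it is comfortable to a few
  thousand basis terms but is not engineered for the 658 008-term
  35-dimensional degree-5 basis at full scale.
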