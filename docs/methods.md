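# Methods

## Model and assumptions

The simulator integrates generalized Lotka-Volterra dynamics on a three-level
trophic ladder (plants / herbivores / carnivores) in which only plants carry a
bare self-limitation term (their logistic `-R_P`).  Interactions are
*reciprocal*: the same preference entry governs the prey's loss and the
predator's (efficiency-discounted) gain.  Under this symmetry the dynamics
converge to a unique globally stable equilibrium from any positive initial
state; the package deliberately excludes non-reciprocal interactions and the
chaos or limit cycles they can produce.  Conversion efficiencies multiply
only the consumption gain — a carnivore's per-capita rate is
`eta_X * sum_j d_aj N_j - u_a`, so the death rate is not rescaled by the
efficiency.  This bracketing is forced by the mean-field effective growth
rate `g_eff_X = -u + eta_X mu_d <N>`, and we verified it dynamically: with
the alternative bracketing a simulated ensemble departs from the mean-field
solution by many standard errors, with this one it agrees within sampling
error.

Preference entries scale as mean `mu/M_prey`, SD `sigma/sqrt(M_prey)` with
the prey pool size, keeping level-summed interactions O(1) as pools grow.
Two sampling dialects share these two moments: Gaussian (entries may be
negative; exactly the statistics the theory assumes — entries are *not*
truncated at zero, which would shift the moments) and uniform on
`[mean - sqrt(3) s, mean + sqrt(3) s]`, which is strictly positive whenever
`mu > sqrt(3) sigma sqrt(M_prey)` and otherwise raises an infeasibility
error.

## Mean-field (cavity) solution

At a replica-symmetric steady state, a typical species' abundance at each
level is `max(0, (g_eff + sigma_g_eff z)/D_eff)`.  All moments reduce to
`w_n(Delta) = int_{-Delta}^inf dx/sqrt(2 pi) (x+Delta)^n e^{-x^2/2}` for
n = 0, 1, 2, evaluated in closed form via the standard-normal pdf/cdf with
arguments clipped to [-40, 40] (beyond which the integrals are 0/saturated at
double precision); adaptive quadrature of the defining integral is kept as a
test oracle only.

The unknowns are the six pooled moments (level means and second moments,
averaged over the full pool including extinct species as zeros — the
convention the theory is written in, and the reason simulated moments are
pooled the same way).  The three susceptibilities are eliminated in closed
form in terms of the survival fractions; their denominators,
`phi_N - r1 phi_X` and `phi_R - r2 phi_N + r1 r2 phi_X`, are exactly the
survival-fraction versions of the competitive-exclusion bounds and must be
positive at a physical solution.  Signs: `chi, nu <= 0` (abundance falls when
a death rate rises), `kappa >= 0`, `D_eff_R >= 1`.

### Numerical strategy

The six residuals are scaled by `max(1, |prediction|)` so means and second
moments (which can differ by orders of magnitude) carry comparable weight,
and the root-finding problem is solved as nonlinear least squares in
log-space, which enforces positivity without explicit constraints and
smooths the landscape.  Iterates that leave the physical packing region do
not abort: the exclusion denominators are floored and a large additive
penalty with a restoring slope pushes the optimizer back.  (An earlier design
sketch made these exclusion penalties a config toggle; they are always on in
the optimizer because it simply does not work robustly without them, while
the public `residuals` function still raises a typed infeasibility error as
its contract states.)  A solution is accepted when the scaled residual norm
drops below 1e-6; the achieved norm is always reported.

Initialization follows the small-simulation trick: integrate one or two
communities of ~10 species per level (a cheap, rough approximation of the
thermodynamic limit), then sample starts between half and the full value of
each pooled statistic.  A purely random multistart and explicit warm starts
(used to chain solutions along parameter scans and derivative stencils) are
also available; all strategies agree on the reference conditions to 1e-5,
consistent with a unique physical branch.

Exact pool-size *ratios* can be set independently of the integer pool sizes
(`r1_override`, `r2_override`): the cavity equations see only ratios, and
integer rounding would otherwise staircase 1-D scans in r1/r2.  Sampling of
finite communities always uses the integer sizes.

## Simulator

`solve_ivp` with LSODA (stiffness-switching; extinct and surviving species
give very different stiffness) at rtol 1e-8 / atol 1e-10.  The state is
clipped at zero inside the right-hand side so integrator round-off cannot
feed negative abundances back into the dynamics.  Steady state is declared
when every species above the extinction threshold has per-capita growth rate
below 1e-5 in magnitude; the horizon starts at t = 200 and doubles up to six
times if the test fails.  The late-time residual is invariably dominated by
species decaying slowly *through* the threshold, and the stiff integrator
takes large steps near equilibrium, so the extensions are cheap (a 168-species
community typically integrates in well under a second).  Non-convergence is a
reported flag, not an exception.  The extinction threshold (default 1e-6,
applied at readout only) is explicit because survivor counts feed the order
parameters.

With zero disorder (`sigma_* = 0`) the consumer levels have per-capita rates
that depend on level totals only, so the totals are pinned but the split
across identical species is neutrally degenerate and inherits the initial
condition; only plants equalize exactly.  Tests of permutation symmetry check
precisely that.

## N-level chains

The generalized solver treats L levels with per-level bare competition D^i,
efficiency eta^i and preference statistics indexed by the consumer level
(level i's matrix has shape `M^i x M^{i-1}` and entry statistics scaled by
the prey pool `M^{i-1}` — the only scaling consistent with the exact
three-level reduction).  Unknowns are the 3L per-level (mean, second moment,
susceptibility) values; the susceptibility here is `chi_i = <dB_i/dg_i>`,
a derivative with respect to the growth rate and hence nonnegative, so the
three-level reduction maps `(kappa, -nu, -chi)` onto it.  Level sizes may be
non-integral because the equations see only the ratios; sampling rounds them.

Two safeguards select the physical branch of the 3L-equation system:

* a plausibility cap — the system admits a spurious "noise blow-up" root in
  which the second moments of adjacent levels sustain each other at enormous
  values (it satisfies the *scaled* residuals to high precision); roots whose
  level means exceed 100x the warm-start anchor are rejected;
* anchor proximity — among all accepted roots across the multistart, the one
  closest in log-space to the warm-start anchor (a directly simulated small
  chain) is returned.

The chi-block of the warm start is obtained by a damped fixed-point iteration
`chi <- (chi + phi/D_eff(chi))/2` with the simulated survival fractions held
fixed; the undamped map alternates and can diverge.

## Observables

* f-ratio `(M_R* + M_X* - M_N*)/(M_N* - M_X*)`: unfilled realized niches in
  the middle level per unfilled niche in the top level.  The packing forms
  `D_eff_X = eta_X sigma_d^2/(eta_N sigma_c^2 r2 f)`,
  `D_eff_N = eta_N phi_N sigma_c^2 r2 f`, `D_eff_R = 1 + 1/f` agree with the
  susceptibility definitions at every solved state (checked to 1e-8).
* Packing order parameter `M_X*/M_N* = r1 phi_X/phi_N`, equal to the
  top-level share of `D_eff_N`; regime threshold 0.5.
* Biomass order parameter `r1 mu_d <X> / (r1 mu_d <X> + eta_N mu_c <R>)`.
  The r1 appears in numerator *and* denominator: we follow the decomposition
  of the herbivore effective growth rate, whose predation term is
  `-r1 mu_d <X>`, rather than a printed variant that drops r1 from the
  denominator and would break the internal decomposition identity.
* Derivative order parameter: central differences of `<N>` with respect to k
  and u at relative step 0.01 (magnitudes, mapped to a [0, 1] fraction; both
  the bottom-up and top-down orientations are exposed).  Stencil solves are
  warm-started from the base solution.
* Toy chain (one species per level, all levels self-limited): the steady
  state is exact by case analysis — interior 3x3 linear solve, then drop the
  carnivore, then all consumers, then everything, accepting the first case
  with positive members and no positive invasion rate (mirroring invasibility
  logic; the precedence order is a design choice since any stable case is
  unique for these dynamics).  A merely feasible case is used as a round-off
  fallback.
* Phase scans chain warm starts across the grid and record per-point solver
  status rather than aborting; finite-size studies compare single-system
  statistics (means and survival fractions) against the size-independent
  cavity solution via mean squared deviation.

## What the synthetic ensembles do and do not emulate

The generator realizes exactly the random-ensemble assumptions of the theory:
i.i.d. preference entries with 1/M scaling, Gaussian growth/death parameters,
no correlations between traits, no structure (blocks, nesting, omnivory,
cross-feeding), no demographic noise, migration or environmental
fluctuations.  Agreement between simulation and theory here therefore
validates the mathematics and the implementation, not the applicability of
the ensemble to any particular empirical food web.  Finite pools deviate from
the thermodynamic limit at O(1/M): at ~200 species per level, pooled moments
still sit 2-9% from the fixed point, which is also why the self-consistency
residual at simulation-derived moments is O(0.1-1) rather than "numerically
zero" — the residual map amplifies moment deviations through differences of
comparable survival fractions in the packing denominators.

## Problem sizes used in the shipped checks

Reference cross-validation uses 50-system ensembles at pools (50, 56, 62);
the uniform-dialect variant 30 systems at (30, 30, 30) with mu = 5; the
order-parameter concordance a 100-point (tests) / 60-point (acceptance
script) Latin-hypercube sweep; the finite-size study 50 systems per size at
M_X = 10 and 50 with r1 = r2 = 0.9; the N-level reduction 20 (tests) / 5
(script) random parameter sets.  These sizes give standard errors a factor of
several below the effects being checked; all tolerances tied to sampling are
expressed in ensemble standard errors (with a binomial floor for survival
fractions, which can have zero sample variance at phi near 1).

## Known limitations

* Replica-symmetric, symmetric-interaction theory only: no stability
  analysis of the RS solution, no RSB, no dynamical mean-field theory, no
  phase-boundary detection.  Near exclusion boundaries (e.g. `M_N* -> M_X*`)
  the packing denominators vanish and both solvers degrade.
* Zero trait diversity (`sigma_c` or `sigma_d` = 0) makes the mean-field
  closure degenerate and is rejected by the solver.
* The N-level branch safeguards are heuristics; they are validated against
  direct simulation on three- and four-level chains but carry no proof.
* The simulator's steady-state test is residual-based; communities with
  near-marginal species can require the full extension schedule, and a
  pathological instance can still be flagged non-converged.
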