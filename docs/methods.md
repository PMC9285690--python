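# Methods

This note documents the model equations as implemented, the stand-in
calibration and its closures, the numerical methods, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Ecological model

State vector: `[Xa, Na, Xs, Ns, Xh, Nh, Nbp]` — biomass (t) and numbers
for anchovy, sardine and halibut, plus the Brown Pelican index. Time in
years; individual masses in tons; the pelican population is dimensionless
(100 = unfished constant-forcing equilibrium).

**Forage species.** Numbers are density independent,
`dN = [r(t) − (M + P + F)] N`; biomass follows the delay-difference
structure `dX = r(t) w_r N + κ(w_inf N − X) − (M + P + F) X`, i.e. new
recruits enter at mass `w_r` and the standing stock grows toward the mean
mass implied by `w_inf` at metabolic rate `κ`. Recruitment forcing is
`r(t) = r̄ exp(A sin(2πt/p + sπ/180 + π) − A²/4)`. The `−A²/4` term is
the standard lognormal bias correction from the variance `A²/2` of a
sine wave; it is exact only to O(A⁴), leaving a period-mean bias of
~0.2% at A = 0.6 (tested to stay below 1%), which induces a slow
downward drift of unfished forage under variability. Because numbers have
no density dependence, unfished forage equilibrium exists only when
`r̄ = M + P*`; the calibration enforces this exactly (see below).

**Halibut.** Recruitment is Beverton–Holt on lagged halibut biomass with
pre-recruit survival: `R = a X_h(t−τ)/(1 + b X_h(t−τ)) · exp(−M_j τ)`.
Predation on the two forage stocks is a multi-prey Type-II response with
a shared denominator, `P_i = C_max α_i X_h / (C_max + α_a X_a + α_s X_s
+ Y)`, which produces prey-switching buffering (`∂P_a/∂X_s < 0`). The
asymptotic mass responds to realized relative consumption
`f = (α_a X_a + α_s X_s + Y)/(C_max + α_a X_a + α_s X_s + Y)` as
`w_inf = w_inf0 (f/f_base)^γ_w` (generalized von Bertalanffy energetics).
The metabolic rate κ appears in the biomass equation only; a
`kappa_in_numbers_loss` switch reproduces the alternative bookkeeping in
which κ also removes individuals.

**Brown Pelican.** `dN_bp = R_bp − M_bp N_bp` with

* depletion index `d = Γ_a X_a/X_a° + Γ_s X_s/X_s° + Γ_other`, where
  `X_i°` are the 200-yr unfished mean forage biomasses under the
  scenario's own forcing (so `d = 1` at those means by construction);
* prey-response scalar `φ(d; θ) = 0` for `d ≤ θ₁`, else
  `θ₃(1−θ₁−θ₂)(d−θ₁) / [(1−θ₁)θ₂(1−θ₃) + θ₃(1−θ₁−θ₂)(d−θ₁)]` clamped to
  [0, 1] — zero up to θ₁, saturating at 1, steepness set by θ₂, θ₃;
  `θ₂ = 0` is the decoupled limit (φ ≡ 1 above θ₁). The form requires
  θ₁ + θ₂ < 1, which the validators enforce;
* reproduction `R_bp = 0.5 e^(−M̄τ_bp) N_bp(t−τ_bp) φ_r ·
  [1 + (Φ−1)(1 − (N_bp(t−τ_bp)/K_bp)^z)]` (female-only accounting; the
  density multiplier is Φ as N→0, 1 at K_bp, floored at 0). By default
  φ_r is evaluated at the prey biomasses lagged by the forage maturation
  delays (`use_lagged_phi_r` switches to current-time evaluation);
* adult mortality `M_bp = M̄ − log φ_v(d)` at current prey, with φ_v
  floored at 10⁻⁶ so the rate stays finite; collapse is reached
  dynamically, never by singularity.

The density exponent z is solved (Brent) so that total net productivity
at saturating prey, `R_bp(N) − M̄N`, peaks at 60% of K_bp; per-capita
productivity is strictly decreasing in N under this density form, so the
"peak" condition is necessarily about total production. The root on the
stronger-compensation branch is used.

## Stand-in calibration

No stock-assessment values ship with the package; the defaults are a
closure-built stand-in with the right orders of magnitude, and a YAML
config (`load_config`) replaces any field. The closures:

1. Target unfished biomasses: anchovy 600,000 t, sardine 800,000 t,
   halibut 20,000 t. Predation at those targets gives P* (a few percent
   of forage M — weak top-down control), and `r̄_i = M_i + P_i*` makes
   the constant-forcing unfished system an exact fixed point (tested to
   machine precision over 200 yr).
2. Forage mean mass at equilibrium is `(r̄ w_r + κ w_inf)/(r̄ + κ)`,
   fixing initial numbers; the halibut Beverton–Holt scale `a` is set so
   surviving recruitment balances adult mortality at the target.
3. Pelican: z from the 60%-of-K rule; K_bp so the unfished equilibrium
   at d = 1 is exactly the index 100. Diet is sardine-dominant
   (Γ = 0.3/0.5/0.2). Reproduction responds to prey more strongly than
   adult survival (θ_r = (0.2, 0.25, 0.8), θ_s = (0.15, 0.2, 0.85)); a
   survival response this size already produces deep pelican dips during
   synchronous prey troughs, and the sensitivity suite removes either
   channel entirely.
4. Economics: prices ~100–120/t (forage) and 8,000/t (halibut),
   q = 0.01, break-even biomasses at 25–40% of unfished levels, and
   quadratic effort costs sized so initial open-access F is ~0.4–0.8/yr.
   Currency is arbitrary; results are reported as ratios or percents.
5. Forcing: amplitude 0.3 (log recruitment), period 25 yr, phases
   starting mid-cycle (90°/270°). The sinusoid integrates into log
   biomass with gain `r̄Ap/2π`, so this amplitude yields unfished biomass
   cycles spanning roughly a factor of 3–7 — boom–bust, but bounded.
   The long-sardine variant doubles the sardine period.
6. Discount rate δ = 0.05 (the sensitivity suite uses 0.10); horizon
   T = 60 yr by default (examples and tests use 50), long-run unfished
   averages over 200 yr.

What the generator emulates: cyclic, environmentally forced forage
productivity; a weakly coupled harvested predator; a tightly
prey-dependent protected seabird; rent-dissipating unmanaged fleets. What
it does not: stochastic recruitment, assessment/implementation error,
sluggish entry–exit, spatial structure, age structure. Tests passing on
this generator show the machinery is correct under the stated study
conditions, not that the numbers transfer to the real fishery.

## Simulation

Fixed-step classical RK4 with method-of-steps semantics: lagged states
(halibut recruitment lag τ_h, pelican lags τ_bp and the forage maturation
lags) are linearly interpolated from the already-computed solution
history, with the constant initial state as pre-history. Feedback
policies (open access, myopic, both sardine rules) are re-evaluated at
every RK4 stage state, so closed-loop runs converge at the usual order;
open-loop efforts are held piecewise constant at the step resolution.
States are clipped at zero after each step (no resurrection; per-capita
rates at N = 0 are 0). Default dt = 0.05 yr; halving dt changes a 40-yr
open-access terminal state by < 0.1%. The integrator is numba-compiled
and deterministic bit-for-bit at fixed dt.

## Optimization

Direct single shooting. Controls are normalized piecewise-constant
efforts (default 2-yr blocks) for the regime's managed species, bounded
by 3× the open-access effort at the scenario's unfished biomass peak;
open-access species are closed algebraically inside the integrator and
closed species are unfished. The objective integrates discounted profit
by trapezoid on the simulation grid and adds a **sustainable-flow
salvage**: profit at the effort the terminal stock could sustain at zero
net growth (capped at the myopic effort), capitalized at δ and
discounted to T. A frozen-state myopic perpetuity was rejected: with no
forage surplus production at equilibrium it overstates continuation
value so badly that "never fish, cash out at T" dominates every fishing
plan. The tail weight e^(−δT) keeps the salvage's influence under ~8%.

The bounded problem is solved with L-BFGS-B from three starts (zero
effort, the open-access path, the myopic path), best-of. The pelican
floor is enforced by a quadratic-penalty homotopy on yearly floor
violations (weight ladder 10 → 10⁵, warm-started) until the samples
clear the floor within 0.05 index units; sequential quadratic
programming proved unreliable from deeply infeasible starts here.
Infeasible regimes (e.g. halibut-only management against a floor that
only forage recovery can deliver) are flagged with a certificate — the
best attainable minimum pelican level across solver output and the
zero/maximal-effort probes. Every returned solution is re-integrated at
half the reporting step; the sup-norm relative state mismatch must stay
below 0.5% or the result is demoted to unverified. No global optimality
is claimed; everything is deterministic (fixed mesh, fixed starts).

The solver is cross-checked on a 1-D reduction (constant recruitment, no
delays, no predation coupling, recruit mass = asymptotic mass, small
quadratic cost) against an independent value-iteration oracle on a
discretized biomass grid; the two values agree within 1%.

## Metrics

"Long-run" = mean over the last recruitment period (variability cases)
or the last 10 yr (constant). Pelican gains are percent changes of that
level against the all-open-access run. Pelican life-years are the
undiscounted integral of the index. The elasticity divides the percent
NPV loss from a floor by the percent life-year gain, both oriented
positive. T_cross is the first floor breach of the unconstrained pelican
path; T_change the first 1%-relative divergence of the effort paths
(effort floor 10⁻⁶ in the denominator).

## Problem sizes used

Tests and examples solve 50-yr horizons at dt = 0.1 inside the optimizer
(reporting/verification at dt = 0.05 and 0.025), 2-yr control blocks
(1-yr in the oracle comparison), 300–500 L-BFGS-B iterations; the DP
oracle uses a 1401-point biomass grid, 201 efforts, dt = 0.1. These sizes
give objective changes < 0.5% under mesh refinement (tested) while
keeping any single solve under a minute.

## Known limitations

* The floor experiments are meaningful under constant forcing; under
  strong cyclic forcing the *unfished* pelican index itself dips below
  any floor set between long-run levels, so a pathwise floor there is
  structurally infeasible regardless of management.
* The bias correction's O(A⁴) residual makes "unfished long-run means"
  horizon-dependent under variability; they are defined as the 200-yr
  means and the depletion index is closed on exactly those.
* Forage numbers have no density dependence, so open-access and optimal
  outcomes hinge on the economic break-evens rather than biological
  compensation — a property of the model family, not of the code.
* Single shooting cannot certify global optima in this nonconvex
  problem; multi-start plus the DP cross-check bound the risk on the
  cases examined.
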