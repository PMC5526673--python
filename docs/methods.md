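# Methods

This note documents the model implemented by `quorumsim`, the numerical
choices behind the two dynamical layers, the defaults and what they mean,
and the limits of what the test suite demonstrates.

## Model definition

**Microscopic process.** A well-mixed population of fixed size `N`; cell
`i` has production degree `p_i ∈ [0, 1]` and fitness (reproduction rate)
`φ(p_i) = 1 − s p_i`, `0 ≤ s < 1`. Events follow the exact stochastic
simulation scheme for a continuous-time Markov process: waiting times are
exponential with total rate `Σ_k φ(p_k)`, the reproducing cell is chosen
proportionally to fitness, its offspring replaces a uniformly chosen
*other* cell (so the population size is strictly constant), and both
offspring — the one occupying the parent's slot and the one replacing the
victim — independently either adopt `R(⟨p⟩)` with probability `λ` or keep
the ancestor's degree. The sensed cue `⟨p⟩` is the average of the
pre-division state. Time units: a population of pure non-producers
experiences one reproduction per individual per unit time.

Two O(1/N) conventions are configurable because they are not uniquely
determined by the verbal model definition: whether the death slot may
coincide with the parent (`death_any`, default off) and whether the cue is
sensed before or after the victim's slot is overwritten (`sense_post`,
default off = pre-division). Neither affects the mean-field limit.

**Noise channels.** Three optional Gaussian perturbation channels with
standard deviations `σ_inherit` (applied to a copied ancestral degree),
`σ_perceive` (applied to the sensed cue before `R`), and `σ_respond`
(applied to `R`'s output); results are clipped to [0, 1]. Gaussian noise
with clipping is the simplest symmetric choice that preserves the state
space; all-zero σ reproduces the noise-free process exactly.

**Response families.** `sinusoidal` `R(x) = x + κ sin(πx)` (monostable
up-regulation; `κ ∈ [0, 1/π]` keeps `R` within [0, 1]); `linear`
(identity); `hill_bistable` `R(x) = x^n (1+K^n)/(x^n + K^n)` — a Hill
sigmoid rescaled so `R(0)=0, R(1)=1`, giving the three-fixed-point
'all-or-none' structure for `n > 1` (the threshold family is a modelling
choice: only its qualitative fixed-point structure matters); `pitchfork`
`R(x) = x + a(x−½) − b(x−½)³`, a generic family whose fixed points undergo
a supercritical pitchfork at `a = 0`, used to probe diverging relaxation
times at response bifurcations; and `table` (linear interpolation of a
two-column table). Fixed points of `R` are found by sign-change bracketing
on a grid of resolution 1e-3, polished by Brent's method to 1e-10;
stability is classified from `R′` with roots at `|R′ − 1| < 1e-6` flagged
*marginal* rather than silently classified.

## Stochastic layer: implementation

The event loop is compiled (numba). Per event the cost is O(1):

- the running sum `Σ p_k` (hence the total rate and `⟨p⟩`) is updated
  incrementally and recomputed in full every `N` events to keep
  floating-point drift far below 1e-9 relative;
- the fitness-proportional parent is drawn by rejection sampling (propose
  uniformly, accept with probability `φ(p_i) ≤ 1`; acceptance ≥ `1 − s`);
- absorption (`all degrees identical` and, for `λ > 0`, `R(p*) = p*`
  within 1e-12) is tested after every event for `N ≤ 512` and every 64
  events for larger populations — the state is frozen once absorbing, so a
  late test only inflates the recorded time by O(events/N). Exact float
  equality is meaningful because the noise-free dynamics only copy values
  or assign `R(⟨p⟩)`.

Runs to a time horizon record full state snapshots on a fixed schedule;
observables (mean, population variance, `B = 50` bin histogram, cluster
count) are derived from snapshots. Runs to absorption use a cutoff
(default 1e4 time units) and report censored runs explicitly.

**Cluster observables.** Subpopulations are gap-separated groups: sorted
degrees are split where consecutive values differ by more than `gap`
(default 0.05, well below the O(0.2) gap the stationary analysis predicts
at reference parameters), ignoring groups below 1% of the population. For
*noisy* dynamics the valley between peaks fills with stragglers and a gap
criterion is blind; the `bimodality` diagnostic instead splits the sample
at the threshold maximizing between-class variance (Otsu's criterion) and
requires a genuine histogram valley (below half the smaller peak) plus at
least 5% mass on each side.

**Seeding.** Every run derives all randomness (initial sample, event
stream, replicate streams) from one master seed via `SeedSequence`;
replicate seeds are logged in ensemble summaries and manifests, so any run
is bit-reproducible from its manifest.

## Mean-field layer: the autoinducer equation

The equation

```
∂t ρ = 2λ φ̄t (δ(p − R(p̄t)) − ρ) + (1 − 2λ)(φ(p) − φ̄t) ρ
```

is integrated on an **adaptive atomic measure** (locations + weights), not
a fixed grid: the sense-and-response term injects delta peaks at the
moving location `R(p̄_t)` and the heterogeneous attractor is purely atomic
with a gap — a grid scheme would smear both by numerical diffusion.

**Time stepping.** Each step of size `dt` applies an operator splitting
that is *exact when the population means are frozen over the step*:

1. replicator tilt: `w_k ← w_k · exp(−(1−2λ) s p_k dt)`, then renormalize
   (the `p̄`-dependent mean terms are absorbed exactly by normalization);
2. sense-and-response: with survival factor `f = exp(−2λ φ̄ dt)`, scale all
   weights by `f` and deposit the mass `1 − f` at `R(p̄_t)` (merged into an
   existing atom within `ε = 1e-4`, weight-weighted centroid).

The scheme is first-order in the coupling through `p̄_t` (the only quantity
frozen per step), and reproduces the two known closed-form solutions to
machine precision at any step size: the `λ = 0` solution
`ρ_0(p) e^{−stp}/Z` (step 1 is its exact propagator) and the `λ = ½`,
linear-`R` solution `y(t) ρ_0 + (1−y(t)) δ(p − p̄_0)`, `y = e^{−φ̄_0 t}`
(`p̄` is conserved there, so freezing it is exact). A plain Euler update of
the weight ODEs was rejected because its O(dt) error at practical step
sizes obscures exactly the oracle comparisons used for validation; the
literal right-hand side (per-atom derivatives + injection rate, summing to
zero) is still exposed as `autoinducer_rhs` for direct property checks.

`dt` adapts so no atom's log-weight moves more than 5% per step, capped at
`dt_max = 1e-2` (the stiffest rates, `2λφ̄ + s`, are O(1)), and lands
exactly on the recording schedule. Atoms below weight 1e-14 are pruned;
total mass is renormalized every step and checked to 1e-9 at every record.
Continuous initial distributions are discretized as 400 equal-mass atoms
at quantile midpoints (equal mass makes transport-distance convergence
uniform). An optional stationarity stop ends integration when the measure
moves less than a threshold in transport distance per unit time.

**Distances.** Convergence diagnostics use the Wasserstein-1 (first-order
transport) distance between atomic measures (via
`scipy.stats.wasserstein_distance`); on [0, 1] it dominates the
bounded-Lipschitz distance, so it is a conservative surrogate for the
distance used in the rigorous mean-field convergence argument, which is
out of scope here and replaced by numerical diagnostics (the empirical
N-particle measure approaches the mean-field solution as N grows).

## Stationary analysis

Closed forms: `β = 2λ/s` (undefined at `s = 0`), `λ_up = s/2`, the
two-atom solution `(p_high, y)` with existence conditions
`0 < p_high ≤ 1`, `0 < y < 1` evaluated literally and violated conditions
reported by name. The boundary `λ = λ_up` is classified homogeneous
(existence requires the strict inequality); the behaviour *at* the
boundary is not asserted anywhere. The `λ → 0` limit of the low-peak
weight, `1 − 1/R′(0)`, is reported when `R(0) = 0` and `1 < R′(0) < ∞`,
with `R′(0)` analytic for built-in families and a central difference
(h = 1e-6) for tables. Linear stability is probed numerically
(perturb-and-integrate), not symbolically: the analytic linear-stability
algebra is out of scope.

The low peak is fixed at `p_low = 0`, valid for initial distributions
whose lowest degree is 0. For initial distributions bounded away from 0
the integrator exhibits the analogous bimodal state with the low peak at
the lowest initial degree; no closed-form checker is provided for that
generalization.

## Experiment drivers and study conditions

Reference parameter point throughout: `s = 0.2`, `κ = 0.2`, with
`λ = 0.05` (heterogeneous phase), `λ = 0.2` (homogeneous phase), `λ = 0`
(no response), uniform initial distribution — the conditions under which
the model's characteristic behaviours are defined. Stochastic study size
is `N = 10⁴` (so `sN ≫ 1` and demographic fluctuations are subordinate);
scaled-down sizes (N ≤ 2000, M ≤ 10) are used where a driver's claim is
qualitative, and the absorption-scaling study uses
`N ∈ {50, 100, 200, 400}`, `M = 50`, where absorption is observable in
minutes — its fitted exponent γ is positive at any scale but its value is
size-dependent, so only the exponential-growth property is asserted.

Driver-specific notes:

- `decay_lambda0` fits the late-time log-log slope of `⟨p⟩(t)` on the
  **ensemble mean** over M replicates (default M = 10). In a single
  finite-N run the late-time mean (`1/(st) ≈ 0.01` by `t = 500`) is
  dominated by demographic drift among the few surviving low-production
  lineages — measured single-run slopes at `N = 10⁴` scatter over roughly
  [−1.6, −0.65] — whereas the ensemble mean recovers the algebraic law.
  The exact closed-form slope is computed alongside by quadrature. The
  window over which the power law holds shrinks with N (it requires
  `1/(st)` well above the finite-population floor).
- `initial_robustness` integrates the mean-field equation to `t = 1600` by
  default: from a quasi-continuous initial distribution the low peak
  condenses algebraically (~1/t, the same physics as the `λ = 0` decay),
  so reaching transport distance ≲ 5e-3 from the two-atom attractor takes
  O(10³) time units. Atomic initial distributions converge exponentially.
- `bifurcation_timescale` uses the pitchfork family at `λ = ½`, where the
  mean obeys `dp̄/dt = φ̄ (R(p̄) − p̄)` and relaxes at rate `≈ φ̄|a|`; the
  fitted exponential rate decreasing toward 0 as `a → 0⁻` demonstrates
  critical slowing down. This family is a generic stand-in for *some*
  polynomial response with a supercritical pitchfork, not a specific
  empirical circuit.

## What the synthetic data does and does not show

All inputs are generated internally (parameter-defined initial
distributions and seeded stochastic dynamics); there is no external data.
Passing tests therefore demonstrate the internal consistency of the model
— stochastic process vs mean-field limit vs closed forms — under the
model's own idealizations: a well-mixed environment sensed instantaneously
through the current population average, fitness exactly affine in the
production degree, response only at division events, constant population
size. They say nothing about whether a real microbial population satisfies
those assumptions; the clipped-Gaussian noise channels probe robustness of
the mechanism, not any measured noise structure.

## Known limitations

- The mean-field attractor from continuous initial distributions is
  approached only algebraically; finite-time integration leaves an O(1/t)
  transport-distance residual (documented above, accounted for in
  tolerances).
- Absorption times at `λ > 0` include a deterministic O(10²–10³) phase in
  which the surviving peak ratchets into the fixed point of `R` to float
  precision; at small N this contribution dominates the fluctuation-driven
  escape, which is why the scaling study reports only γ > 0.
- No spatial structure, explicit autoinducer chemistry, or variable
  population size; no symbolic stability/bifurcation analysis.
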