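# Methods

This note documents the three models' assumptions, the parameters that
matter (with defaults and the reasoning behind them), the synthetic
substrate they run on, and the numerical conventions. Everything stated
here is computed by the test suite or the example scripts; nothing is
imported from external data.

## Panic buying: a visibility-scaled threshold cascade

### Model

Consumer i draws a base threshold z_i ~ N(μ, σ²) and acts under the scaled
threshold t_i = z_i / v, where v > 0 is the product's visibility.
Thresholds are in *panic-fraction* units: i panic buys once the fraction of
consumers already panic buying reaches t_i. Panic is absorbing. Updates are
synchronous best responses; since the panicking set only grows, the process
terminates in at most n rounds at a deterministic equilibrium given the
drawn thresholds.

The fraction-units convention follows the classic threshold-model
tradition; the alternative (absolute counts) only rescales μ and σ.
Synchronous updating makes the equilibrium a pure function of the drawn
thresholds, which is what the analytic oracle describes; asynchronous
ordering would reach the same fixed point because the best-response map is
monotone.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| μ (`threshold_mean`) | 0.35 | panic fraction | tipping region sits mid-grid (v ≈ 0.6) |
| σ (`threshold_sd`) | μ/Φ⁻¹(0.9) ≈ 0.2731 | panic fraction | makes Φ(−μ/σ) = 0.10 exactly: 10% of consumers trigger at the initial state |
| v (`visibility`) | 1.0 | dimensionless | the swept quantity; grid 0.01…2.00 in the sweep preset |
| n (`n_consumers`) | 1000 | consumers | large enough for ±1 pp replicate noise; 10⁵ used for oracle checks |

The 10% trigger is the model's one fixed calibration; μ and σ are
otherwise free and exposed. With these defaults the equilibrium stays near
the trigger for v < 0.5 (fixed points 0.116 at v = 0.2, 0.163 at v = 0.5)
and exceeds 0.99 for v ≥ 1 — the low-/high-visibility regimes.

### The analytic oracle

The large-n equilibrium is the smallest fixed point f* ≥ Φ(−μ/σ) of
f = Φ((v·f − μ)/σ). `analytic_fixed_point` iterates from f₀ = Φ(−μ/σ); the
map is nondecreasing and the iterate sequence is monotone nondecreasing,
so it converges to f* (tolerance 1e-10). Simulation–oracle agreement is
asserted within 3 Monte-Carlo standard errors of the replicate mean at
n = 10⁵, floored at the one-consumer resolution 1/n: simulated equilibria
are multiples of 1/n, so at v = 2 — where the fixed point is within 10⁻⁹
of 1 — every replicate lands on exactly 1.0 and the sample SE collapses to
zero while the true discrepancy is far below anything the simulation can
resolve.

## Conformity: asynchronous social learning on a small world

### Substrate

The network is the classic small-world construction: a ring lattice with
N = 500 nodes and k = 10 links per node (each node tied to its five
nearest neighbors per side), each lattice edge independently rewired with
probability p by detaching its clockwise endpoint and reattaching to a
uniformly random node; self-loops and duplicates are redrawn so the edge
count is exactly Nk/2. Rewiring may disconnect the graph; isolated agents
skip their turns. Node indices are 0-based.

Initial scores are a smooth field on the ring: Gaussian white noise,
circular moving-average window `smoothness` = 10, normalized to unit
marginal variance, scaled by `amplitude` = 1 and shifted so that exactly a
`anti_fraction_target` = 25% minority is negative. The shift is the
realization's own 25% quantile: the pro/anti split is the experiments'
controlled initial condition, and leaving it to a fixed offset would let
it scatter widely (the smoothed field has only ~N/smoothness effective
degrees of freedom). Supplying `mean_level` explicitly restores the
fixed-offset behavior. Window 10 makes anti clusters comparable in extent
to the k = 10 neighborhood, so nearly every anti agent has at least some
pro contacts — the regime in which the rewiring probability can decide
between entrenchment and conversion.

### Learning dynamics

Per period: one uniform agent observes one uniform contact and moves its
score by θ = 0.02 toward the contact's behavior (up if the contact does
it). A move that would leave the agent's permissible range
[x_i − r_i, x_i + r_i] is rejected; `clamp_to_boundary=True` clamps instead
(off by default, keeping the literal reject-if-outside rule). Behavior is
score > 0, re-derived after every update; a score of exactly 0 counts as
not doing the behavior.

Conformism half-ranges r_i ~ U(0.5, 2.0) in score units. The lower bound
matters: agents whose entire range is negative can never convert, and with
typical anti scores around −0.6 a lower bound of 0.5 leaves only ~2–3% of
agents permanently anti — consistent with "almost all" (not all) agents
ending pro at high rewiring. θ = 0.02 means crossing a typical range takes
~100+ observations, so behavior changes by accumulated social evidence,
not single encounters.

Horizon: 2000 expected updates per agent (10⁶ periods at N = 500), with
early convergence declared after 200 consecutive expected updates per
agent without any behavior flip. The long horizon is needed because change
propagates as fronts at pro/anti cluster interfaces, with waiting times of
hundreds of periods per converted agent; a short stall window would freeze
the fronts mid-motion and understate consensus.

With these settings, 20-seed means of the final anti share are
0.153 / 0.105 / 0.070 at p = 0.1 / 0.2 / 0.3, with the final/initial score
variance ratio 2.9 at p = 0.1 (polarization: agents pile up near range
boundaries) and 93% of agents ending positive at p = 0.3 (consensus).

## Conspiracy belief: modified SIR with assortative matching

### Model

Compartments: unsusceptible (never believes; constant count), susceptible,
infected (believes), recovered. Transitions are one-directional S→I→R; no
reinfection. Per period, individual i is drawn uniformly; if i is infected
it is matched to another infected with probability m (uniform fallback if
i is the sole believer), otherwise — and always when i is uninfected — to
a uniform other. Exactly one pair rule applies per interaction:

1. susceptible × infected → the susceptible becomes infected with
   recovery probability reset to p₀;
2. (unsusceptible or recovered) × infected → the infected recovers with
   its current probability p_it; under cumulative influence a *failed*
   attempt multiplies p_it by 1.1 (capped at 1) — attempt first, amplify
   on failure, which reproduces the 5% → 5.5% single-interaction
   arithmetic while leaving a successful recovery's probability moot;
3. infected × infected → both probabilities multiplied by 0.9
   (skipped under constant recovery);
4. anything else → no change.

Both members of the pair update symmetrically; being the drawn individual
confers no role beyond the matching rule. Time is reported as mean
interactions per individual (2 × periods / N).

### Parameters and horizon

Defaults: N = 1000, 100 susceptible, 10 initial believers, m = 0.5,
p₀ = 0.05, reinforcement 0.9, influence 1.1. The horizon is 500 mean
interactions per individual (250 periods per capita). The shorter horizon
of 200 mean interactions leaves the burn-out scenarios visibly unfinished —
without reinforcement only ~37% of 30 seeded runs reach extinction by then,
and ~7% of baseline runs still hold uninfected susceptibles — whereas by
500 both events occur in 30/30 runs while baseline and reduced-m runs have
long plateaued (believer cores whose recovery probabilities have decayed
below ~10⁻⁹ are effectively permanent). Runs stop early once infected = 0
(an absorbing state) and the trajectory is padded with its constant tail.

Behavior across scenarios (30 seeds): baseline retains a believer core of
~51 of the 100 susceptibles; m = 0.2 retains far fewer (~16); constant
recovery goes extinct (mean ≈ 212 interactions); cumulative influence goes
extinct earlier (mean ≈ 166) with a lower infection peak.

## Reproducibility conventions

* Every stochastic routine takes either an explicit `numpy` Generator or a
  `seed` field; identical seeds give bit-identical outputs.
* Replicate runs derive child seeds as
  `SeedSequence([master_seed, replicate_index])` truncated to 31 bits
  (the panic sweep uses `[master_seed, v_index, replicate]`); a run's
  manifest records the master seed and children, and re-running from the
  manifest reproduces CSV bodies byte-for-byte (floats serialized at 9
  significant digits).
* The conformity model draws four independent child streams from its seed
  (network, scores, ranges, learning), so the same substrate can be
  re-examined under different dynamics.

## What the generators do and do not emulate

All populations are synthetic and exchangeable: there are no demographic
covariates, no real purchasing or survey data, and no fitted parameters.
The score field emulates homophily only as smooth spatial correlation on a
ring; real attitude distributions are neither Gaussian nor
one-dimensional. The contagion model is well-mixed apart from the single
assortativity parameter — there is no network structure in who can meet
whom. Passing tests therefore demonstrate that the stated mechanisms
produce the stated collective outcomes under the stated conditions, not
that these parameter values describe any real population.

## Known limitations

* The panic model has no prices, inventories, or multiple products; the
  cascade is one-shot with absorbing panic.
* The conformity outcomes (final anti shares) depend quantitatively on the
  free parameters θ, the conformism interval, and the score field's
  correlation length; only the qualitative ordering across rewiring
  probabilities is robust across reasonable choices.
* Near the panic model's tipping visibility (v ≈ 0.6) finite-n equilibria
  are bimodal between the low and high fixed-point branches; replicate
  means there have high variance by nature.
* The contagion model treats "equilibrium" operationally (extinction, or a
  frozen believer core at the horizon); believers with tiny but nonzero
  recovery probabilities would recover on astronomically long timescales.
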