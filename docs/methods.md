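# Methods

## The game model

One player repeatedly harvests from a depletable pool. State is the current
resource level; a round consists of (i) a harvest `a ∈ [0, s]`, (ii)
removal of the harvest, (iii) stochastic replenishment of the remainder
`r = s − a` by a fraction `f` drawn fresh each round from N(μ, σ²),
clamped below at 0, with the pool truncated at the cap:

    s' = min(cap, r + round(r · f)),   f ~ max(0, N(0.15, 0.03²))

Defaults: cap 60, initial pool 60, at most 70 rounds, $0.005 per point
(bonus capped at $3.00), and a waiting penalty of 6 s for every round
between the depletion round and round 50 (so depleting at round 10 costs
240 s). The penalty is recorded in seconds, never slept.

Committed conventions the game description leaves open:

- **Integer states.** The pool is displayed as discrete points, so resource
  and harvests are integers and replenishment rounds half-to-even (fixed
  for reproducibility). A continuous mode (`integer_mode=False`) exists for
  sensitivity analysis but the solver and cohorts use integer states.
- **Clamp, not resample**, for negative replenishment draws — a −5σ event
  at the defaults, so the clamp is never active in practice.
- **Exhaustion** means the post-harvest remainder is 0; since replenishment
  is proportional to the remainder, 0 is absorbing and this is the only way
  the pool empties. `rounds_lasted` counts the round of the final harvest.

## The optimal policy

The game is a Markov decision process with reward = harvest. Because the
transition depends on (state, action) only through the remainder, the
kernel is a 61×61 matrix over remainders and a Bellman backup is one
matrix–vector product plus a running maximum (`T h(s) = s + max_{r≤s}
(w(r) − r)`, `w = P h`).

**Kernel.** The default kernel is exact: in integer states,
`round(r·f) = k` exactly when `f ∈ [(k−½)/r, (k+½)/r)`, so each integer
replenishment carries a Gaussian CDF cell mass, with the mass at or beyond
the cap lumped into the capped state and clamped negative draws absorbed
into the `k = 0` cell. An alternative node-quadrature kernel
(`kernel_method="nodes"`) is provided but needs several hundred nodes to
resolve the ≈0.026 points/round gain gap between targets 50 and 51 —
coarser node grids flip the prescribed target between 50 and 51, which is
why the exact kernel is the default.

**Average-reward solver** (primary; players did not know the horizon).
Relative value iteration with a damping factor 0.5 as an aperiodicity
transform, reference state 60, span tolerance 1e−10. The chain is
multichain: the empty pool — and tiny pools whose rounded replenishment is
always zero (e.g. `round(1·f) = 0`) — earn long-run gain 0, while every
state that can climb earns the optimal gain. The iteration therefore lets
the relative values of those dead states drift downward (each sweep they
fall behind by the gain, exactly the penalty that teaches the greedy policy
never to run the pool down) and tests span convergence over the growing
states only, identified by upward reachability through the kernel support.

Ties in the greedy action (within 1e−9) break toward the smaller harvest,
making the policy unique and conservative. The solved policy is verified to
be of threshold form rather than assumed: harvest `max(0, s − 51)`. An
independent stationary-state oracle — the recurrent per-round reward of a
harvest-to-T rule is `E[min(cap − T, round(T·f))]`, computable from normal
CDFs with no MDP machinery — confirms both the argmax (51) and the gain
(7.4987) to 1e−6.

With σ = 0 the steady-state rates tie at 8 points/round for T ∈ {50, 51,
52} and the bias (transient reward) ordering under smaller-harvest
tie-breaking commits to target 52; this case doubles as a solver test.

**Discounted mode** (value iteration) models impatience: the target is
non-increasing in 1 − γ (51 at γ ≥ 0.99, 50 at γ = 0.9, harvest-everything
at γ = 0.7). **Finite-horizon mode** (backward induction, horizon 70)
models the known-termination variant; in the last round it harvests the
full pool at every state.

## Psychometrics

Summated scales at score level: AUDIT 10 items 0–4 (total 0–40), GHQ-12
twelve items Likert 0–3 (total 0–36; the 0–36 scale is the one consistent
with a cohort mean near 15), WHO-5 five items 0–5 reported raw (0–25).
The financial-literacy battery has 9 items with a configurable per-item
range (default 0–7, total 0–63): the published cohort mean of 34.3 cannot
be reconciled with the standard 21-point short-form scoring, so the map is
a parameter rather than a guess.

The ED50 staircase walks a 31-step geometric ladder of delays from 1 hour
(1/24 day) to 25 years (9125 days), committed as a data file. Probing
starts at the ladder midpoint (≈19.5 days); each "now" choice moves the
next probe to a shorter delay, each "delayed" choice to a longer one, with
index steps 8, 4, 2, 1, 1 clamped at the ladder ends. The final index is
the ED50; k = 1/ED50 in 1/days and analyses use the natural log. Natural
log in day units is the only convention under which the published cohort
means (−4.4, −3.34) fall inside the reachable range [ln(1/9125), ln 24] =
[−9.12, +3.18]. Monotonicity (flipping any "now" to "delayed" never
shortens ED50) follows from the clamped staircase and is property-tested.

Cronbach's α uses the variance form `k/(k−1)·(1 − Σσᵢ²/σ_total²)` with
n−1 denominators. Note α = 1 only for essentially tau-equivalent items
(equal true-score scale); positively rescaled copies of one item give
α < 1, which the tests assert in closed form.

## Synthetic cohorts

Traits are drawn from a Gaussian copula: the target Spearman matrix is
mapped to the latent Pearson matrix by `2 sin(πρ/6)`, Cholesky-factored
(with a PSD check that reports the nearest PSD matrix on failure), and the
normal marginals are scaled to the preset mean/SD, rounded (instrument
totals) and clipped to instrument ranges. Clipping at zero induces
right-skew comparable to what SDs of the order of the means imply. Only the
discounting–AUDIT rank correlation (0.41) and a negative distress/
well-being placeholder (−0.45) are non-zero by default; other
cross-correlations are configurable placeholders, since no published values
exist for them.

Behaviour model (a declared construction, with no claim of cognitive
realism): each agent is a noisy threshold harvester. Their target is

    target = 18 − Σ_t coef_t · z_t + N(0, 4),  clipped to [0, 60]

with per-round execution noise N(0, 8) on the intended harvest. Exact
threshold policies never exhaust the pool (the remainder never drops below
the target), so the per-round noise is what produces early exhaustion: an
agent's per-round exhaustion hazard is roughly Φ(−target/8), giving a
smooth spectrum from instant depletion (target ≈ 0) to guaranteed
full-length survival (target ≳ 25). Default coefficients (AUDIT 7, GHQ-12
2.5, WHO-5 −2.5, financial literacy −2.5, log k 4 for the primary preset;
AUDIT 7, log k 4 for the replication preset; log k 6 for the
known-termination preset) are calibrated — and pinned — so the primary
preset yields Spearman(AUDIT, rounds lasted) in [−0.7, −0.45]; observed
values sit near −0.62, with ~43% full-length survivors and ~35% depleted by
round 10.

What the generator does **not** emulate: learning within the game (agents
are stationary), the discreteness of real questionnaire response processes
(totals are rounded Gaussians, not item sums), any causal pathway between
traits and behaviour (the linear map is a construction), and the exact
outcome marginals of human play. Passing tests therefore show that the
pipeline's statistics behave correctly on data with this structure — not
that human data would produce these numbers.

## Statistics

- **Spearman**: Pearson correlation of mid-ranks; two-sided p from the t
  approximation with n − 2 df (exact permutation is impractical at n = 400;
  at n = 200 the empirical size is 0.052 against nominal 0.05).
- **Partial Spearman** (one covariate): rank-transform all three vectors,
  residualize both rank vectors on the covariate's ranks by least squares,
  correlate the residuals; df = n − 3. A constant covariate falls back to
  the plain correlation with a warning.
- **Breusch–Pagan**: LM = n·R² of the auxiliary least-squares regression of
  squared residuals on the predictors, against χ²(k). A degenerate
  auxiliary total sum of squares (squared residuals constant to rounding)
  scores 0 rather than dividing noise by noise.
- **Quantile regression**: exact minimization of the pinball loss
  Σ ρ_τ(y − a − b·x) as a linear program, solved through its dual
  (maximize y'λ subject to X'λ = 0, λ ∈ [τ−1, τ]ⁿ), whose equality-row
  marginals are the coefficients; verified identical to the primal
  formulation to 1e−15 and to an established exact solver to 1e−6. The
  fitted solution satisfies the balance condition #(resid<0)/n ≤ τ ≤
  #(resid≤0)/n. Confidence intervals are participant-resampling bootstrap
  percentiles (default 1000 resamples, seeded); this is a deliberate
  substitution for the rank-inversion intervals of the classical
  literature, chosen for transparency, and is documented rather than
  presumed equivalent. With outcomes censored at the 70-round ceiling,
  coefficients above τ ≈ 0.75 flatten toward zero for rounds lasted — the
  best performers survive the whole game regardless of traits — so bands
  there should be read with care.
- **Replenishment-luck control**: per participant, the mean drawn
  replenishment fraction over the first min(w, rounds lasted) rounds for
  w ∈ {1, 2, 3, 5, 10, 20, 50, 70}, rank-correlated against both outcomes.
  On default cohorts these are null; note a single n = 400 cohort gives
  each null correlation an SD of ≈0.05, so the tests bound the across-seed
  mean (SD ≈ 0.022 over five seeds) by 0.1 rather than a single draw's
  maximum.

## Problem sizes and tolerances

Solver: 61 states, span tolerance 1e−10, damping 0.5 (converges in ~2 s).
Monte-Carlo policy sweep: 5000 games per threshold, normal-approximation
95% CIs. Size calibration: 2000 null replications at n = 200. Bootstrap
sizes in tests are 150–500 resamples; the pipeline default is 200 and the
library default 1000. The end-to-end `replicate` presets use the cohort
sizes of their study arms (400 / 200 / 100).

## Known limitations

- The financial-literacy scale is a convention, not a reconstruction.
- Cross-trait correlations beyond discounting–AUDIT are placeholders.
- Bootstrap rather than rank-inversion quantile CIs (see above).
- The average-reward solver's dead-state handling assumes upward
  reachability is monotone in the resource level, which holds for
  proportional replenishment but would need revisiting for non-monotone
  replenishment rules.
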