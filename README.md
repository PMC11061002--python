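# harvestgame

A research package for studying individual differences in sustainable
resource management with a single-player stochastic harvesting game. It
bundles four things that are usually scattered across analysis scripts:

1. **The game.** A player faces a pool of 60 resource points. Each round
   they harvest any number of points; the remainder replenishes by a random
   fraction drawn from a Gaussian (μ = 15%, σ = 3% of the remainder),
   truncated so the pool never exceeds 60. The game ends when the pool is
   emptied or after 70 rounds. Harvested points pay $0.005 each (bonus
   capped at $3.00), and emptying the pool before round 50 costs a waiting
   penalty of 6 s per round remaining to round 50.
2. **Its optimal policy.** The game is a Markov decision process on integer
   states *s* ∈ {0, …, 60} with actions *a* ∈ {0, …, s}, reward *a*, and
   transition *s′* = min(60, r + round(r·f)), r = s − a, f ~ N(0.15, 0.03)
   clamped at 0. Average-reward dynamic programming (relative value
   iteration) yields a threshold rule: **harvest nothing at 51 points or
   below; above 51, harvest down to 51.** Discounted and finite-horizon
   solvers model impatient agents and the known-termination variant.
3. **Psychometrics.** Score-level implementations of AUDIT (0–40), GHQ-12
   (0–36), WHO-5 (0–25) and a configurable financial-literacy battery, the
   5-trial adjusting-delay ED50 staircase (31-step geometric delay ladder,
   1 hour to 25 years; k = 1/ED50, analyses use ln k), and Cronbach's α.
4. **The analysis pipeline**, applied to synthetic cohorts whose traits
   drive harvesting behaviour: Spearman and partial Spearman rank
   correlations, the Breusch–Pagan heteroskedasticity test, exact
   pinball-loss quantile regression over τ = 0.05, …, 0.95 with z-scored
   predictors and bootstrap confidence bands, and a control analysis
   relating outcomes to each participant's experienced replenishment luck.

The synthetic-cohort generator emulates the statistical shape of the human
data this design produces — printed marginals, a 0.41 rank correlation
between discounting and AUDIT, outcome heterogeneity from instant
exhaustion to full-length sustain, and heteroskedastic rewards — so the
whole pipeline can be exercised and validated without any participant data.

## Worked example

```python
from harvestgame import (GameConfig, build_transition_model, solve,
                         exp1_config, simulate_cohort, spearman,
                         partial_spearman, breusch_pagan)

table = solve(build_transition_model(GameConfig()))
print(table.threshold, table.target, round(table.gain, 3))
# 51 51 7.499

records = simulate_cohort(exp1_config(rng_seed=42))
r = spearman(records["audit"], records["rounds_lasted"])
print(f"rs({r.df}) = {r.rho:.2f}")
# rs(398) = -0.63
```

The first block solves the game: the long-run optimal player leaves 51
points in the pool and earns about 7.5 points per round. The second builds
a 400-agent synthetic cohort and recovers the planted negative association
between hazardous drinking and rounds sustained; `partial_spearman(...,
records["log_k"])` shows it survives controlling for delay discounting
(rs(397) = −0.56), and `breusch_pagan(records["total_rewards"],
records["rounds_lasted"])` rejects homoskedasticity (LM = 81.6,
p = 1.7e−19) because long-lasting agents diverge in how much they harvest.

Each script in `examples/` demonstrates one capability end to end:
`play_game.py`, `optimal_policy.py`, `psychometric_scoring.py`,
`synthetic_cohort.py`, `analysis_pipeline.py`. A thin CLI wraps the same
functions (`harvestgame simulate|solve-mdp|generate-cohort|analyze|replicate`);
`replicate` chains all stages and writes a manifest with per-stage seeds
and SHA-256 digests so runs are byte-for-byte reproducible.

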