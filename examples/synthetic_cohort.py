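"""Generate a synthetic cohort whose traits drive harvesting behaviour.

Traits follow a Gaussian copula with the primary study preset's marginals
(e.g. AUDIT 9.8 +/- 10.1, log k -4.4 +/- 2.8, rank correlation 0.41
between them). Each participant's trait profile sets the target of a noisy
threshold-harvesting agent, and one seeded game produces the outcomes.
"""

from scipy import stats

from harvestgame import exp1_config, simulate_cohort

records = simulate_cohort(exp1_config(rng_seed=42))

print(f"n = {len(records)} participants")
print(records[["audit", "ghq12", "who5", "finlit", "log_k"]].describe()
      .loc[["mean", "std"]].round(2))

survivors = (records["rounds_lasted"] == 70).mean()
early = (records["rounds_lasted"] <= 10).mean()
print(f"\nfull-length survivors: {survivors:.0%}; depleted by round 10: {early:.0%}")

rho = stats.spearmanr(records["audit"], records["rounds_lasted"])
print(f"Spearman(AUDIT, rounds lasted) = {rho.statistic:.2f} (p = {rho.pvalue:.2g})")

# Hazardous drinking lowers the agent's harvesting target, so high-AUDIT
# agents exhaust the pool earlier - the planted negative association the
# analysis pipeline is expected to recover.
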