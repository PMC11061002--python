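"""Run the full statistics battery on a synthetic cohort.

Spearman and partial Spearman correlations, the Breusch-Pagan test of
heteroskedasticity of total rewards in rounds lasted, quantile-regression
profiles over the 0.05..0.95 grid, and the replenishment-luck control.
"""

from harvestgame import (
    breusch_pagan,
    exp1_config,
    mean_replenishment_control,
    partial_spearman,
    quantile_regression,
    simulate_cohort,
    spearman,
)

records, trajectories = simulate_cohort(
    exp1_config(rng_seed=42), return_trajectories=True
)

r = spearman(records["audit"], records["rounds_lasted"])
print(f"AUDIT x rounds lasted:      rs({r.df}) = {r.rho:.2f}, p = {r.p_value:.2g}")

pr = partial_spearman(records["audit"], records["rounds_lasted"], records["log_k"])
print(f"  controlling log k:        rs({pr.df}) = {pr.rho:.2f}, p = {pr.p_value:.2g}")

bp = breusch_pagan(records["total_rewards"], records["rounds_lasted"])
print(f"Breusch-Pagan (rewards ~ rounds): LM = {bp.statistic:.1f}, p = {bp.p_value:.2g}")

fit = quantile_regression(
    records["rounds_lasted"], records["audit"], tau=0.5,
    n_boot=500, seed=1, normalize=True,
)
print(
    f"median quantile regression: {fit.coef[0]:+.1f} rounds per SD of AUDIT "
    f"(95% CI [{fit.ci_low[0]:.1f}, {fit.ci_high[0]:.1f}])"
)

control = mean_replenishment_control(trajectories, records)
print(
    "replenishment-luck control: max |rho| over windows = "
    f"{control['rho'].abs().max():.2f}"
)

# The partial correlation shows the drinking-outcome link is not explained
# by discounting; the Breusch-Pagan rejection mirrors the fan-shaped
# rewards-vs-rounds scatter; the near-zero control correlations show that
# outcomes track the agents' policies, not their luck with replenishment.
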