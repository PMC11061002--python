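"""Score the questionnaires and the delay-discounting staircase.

Instrument totals are summated scales; the 5-trial adjusting-delay
staircase walks a 31-step geometric ladder of delays (1 hour to 25 years)
and returns the delay at which $1,000 loses half its value (ED50), with
the hyperbolic discount rate k = 1/ED50 and its natural log.
"""

import numpy as np

from harvestgame import INSTRUMENTS, cronbach_alpha, run_ed50_elicitation, score_instrument

audit_responses = [2, 3, 1, 0, 0, 1, 0, 2, 0, 1]
print("AUDIT total:", score_instrument(audit_responses, INSTRUMENTS["AUDIT"]))

for label, answers in [
    ("all 'now'     ", ["now"] * 5),
    ("mixed         ", ["now", "delayed", "now", "delayed", "now"]),
    ("all 'delayed' ", ["delayed"] * 5),
]:
    profile = run_ed50_elicitation(answers)
    print(
        f"{label} ED50 = {profile.ed50_delay:9.3f} days, "
        f"log k = {profile.log_k:+.2f}"
    )

# Internal consistency of simulated correlated items:
rng = np.random.default_rng(0)
latent = rng.normal(size=500)
items = np.column_stack([latent + rng.normal(0, 0.5, 500) for _ in range(10)])
print(f"Cronbach's alpha of 10 parallel items: {cronbach_alpha(items):.2f}")

# Higher log k means steeper discounting (rewards lose value quickly with
# delay); the staircase bounds log k between ln(1/9125) = -9.12 and
# ln(24) = +3.18.
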