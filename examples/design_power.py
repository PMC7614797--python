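"""Closed-form design power checks for the simulation study's settings.

The study's sample size of 1000 (500/arm) was chosen so a two-sample
t-test detects a 0.2 SD treatment effect with 88% power, and the chosen
interaction effects give 35% / 88% power for the 2x2 interaction contrast.
"""

from stratsim import power_interaction, power_two_sample_t

p = power_two_sample_t(n_per_arm=500, delta=0.2, sd=1.0, alpha=0.05)
print(f"two-sample t-test, 500/arm, delta = 0.2 SD: power = {100 * p:.1f}%")

for beta_tx in (0.2, 0.4):
    p = power_interaction(n_per_cell=250, beta_tx=beta_tx, sd=1.0, alpha=0.05)
    print(f"2x2 interaction contrast, 250/cell, beta_tx = {beta_tx}: "
          f"power = {100 * p:.1f}%")
# These exact noncentral-t values anchor the simulated powers: the
# true-strata analyses should sit near them, degraded analyses below.
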