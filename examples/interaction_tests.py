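"""Treatment-by-covariate interaction tests under misclassification.

Testing for a subgroup effect on the misclassified randomisation strata
attenuates the interaction (errors mix the subgroups), collapsing power;
the true strata preserve it.  20% equal errors, full discovery, beta_x=1.
"""

from stratsim import Adjustment, Analysis, ScenarioConfig, run_scenario

REPS = 2000
for beta_t, beta_tx in ((0.1, 0.2), (0.0, 0.4)):
    cfg = ScenarioConfig(beta_t=beta_t, beta_tx=beta_tx, beta_x=1.0,
                         error_rate=0.2)
    analyses = (
        Analysis("interaction", Adjustment.RANDOMISATION),
        Analysis("interaction", Adjustment.TRUE),
    )
    res = run_scenario(cfg, analyses, REPS, seed=0)
    print(f"interaction beta_tx = {beta_tx} "
          f"(design power {'35%' if beta_tx == 0.2 else '88%'}):")
    for a in analyses:
        s = res.summaries[("interaction", a.covariate.value, "interaction")]
        print(f"  {a.covariate.value:22s} power {s.rejection_pct:5.1f}%  "
              f"interaction bias {s.bias:+.3f}")
# The randomisation strata under-estimate the interaction (bias toward 0)
# and lose most of the power; the true strata are unbiased and near the
# design power.
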