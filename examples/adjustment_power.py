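"""Power of the adjustment strategies when all errors are discovered.

Scenario: 20% misclassification equal across strata, very strong covariate
(beta_x=3), real treatment effect beta_t=0.2, full error discovery.  The
true strata recover the power lost to misclassification; the randomisation
strata do not.
"""

from stratsim import Adjustment, Analysis, ScenarioConfig, run_scenario

REPS = 2000
cfg = ScenarioConfig(beta_t=0.2, beta_x=3.0, error_rate=0.2)
analyses = tuple(
    Analysis("treatment", a)
    for a in (Adjustment.NONE, Adjustment.RANDOMISATION, Adjustment.TRUE)
)
res = run_scenario(cfg, analyses, REPS, seed=0)

print(f"power to detect beta_t = 0.2 (R = {REPS} simulated trials):")
for a in analyses:
    s = res.summaries[("treatment", a.covariate.value, "treatment")]
    print(f"  {a.covariate.value:22s} {s.rejection_pct:5.1f}%  "
          f"(bias {s.bias:+.3f}, EmpSE {s.emp_se:.3f}, MCSE {s.mcse_rejection:.2f})")
# All three are unbiased; they differ in precision.  Adjusting for the true
# strata gives ~88% power vs ~52% for the misclassified randomisation strata
# and ~40% unadjusted.
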