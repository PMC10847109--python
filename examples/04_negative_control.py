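"""Male negative control for parity.

A generator with a female-only causal parity effect on one metabolite and
a shared (education-driven) confounded association on another. Comparing
unadjusted children-count associations between sexes classifies the first
as causal-suggestive and the second as bias-suggestive.
"""

import reprotri as rt
from reprotri.negcontrol import verdicts_to_frame
from reprotri.synthdata import null_config

cfg = null_config(n_females=8_000, n_males=8_000, n_snps_per_exposure=10,
                  n_metabolites=10, n_factors=6, seed=3)
cfg.causal_effects = {"parity": {"VLDL_P": 0.1}}
cfg.confounder_effects = {("education", "parity"): 0.5, ("education", "GlycA"): 0.12}
cohort = rt.simulate_cohort(cfg)

verdicts = rt.run_negative_control(cohort.table, ["VLDL_P", "GlycA"], model="model1")
frame = verdicts_to_frame(verdicts)
print(frame[["metabolite", "beta_f", "beta_m", "same_direction",
             "ci_overlap", "classification"]].round(4).to_string(index=False))
# VLDL_P: clear female slope, null male slope -> causal-suggestive.
# GlycA: similar slopes in both sexes with overlapping CIs -> the
# association is what shared confounding looks like.
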