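"""Simulate a study-like cohort and look at its structure.

Builds the default synthetic cohort (population-cohort age structure,
reproductive exposures instrumented by independent SNPs, a factor-driven
metabolite panel, menopause missingness tied to younger age) and prints
the descriptive quantities the generator is calibrated to.
"""

import reprotri as rt

cfg = rt.SimulationConfig(n_females=20_000, n_males=15_000, seed=1)
cohort = rt.simulate_cohort(cfg)
fem = cohort.females

print(f"cohort: {len(cohort.table):,} rows ({len(fem):,} female)")
print(f"age at baseline: mean {fem['age_baseline'].mean():.1f}, sd {fem['age_baseline'].std():.1f}")
print(f"menarche age:   mean {fem['menarche_age'].mean():.1f}, sd {fem['menarche_age'].std():.1f}")
print(f"children:       mean {fem['n_children'].mean():.2f}")
print("menopause status fractions:")
print(fem["menopause_status"].value_counts(normalize=True).round(3).to_string())
miss = fem["menopause_age"].isna().mean()
print(f"missing menopause age: {miss:.1%} (premenopausal + surgical women)")
# The ~37% missing fraction and the younger age of premenopausal women are
# what later drive the selected-vs-full sample contrast for menopause.
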