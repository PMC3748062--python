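"""Monte-Carlo check of the closed forms and the type-II-error story.

The "masked-subgroup" preset draws 1000/1000 cohorts in which 20% of cases form a
subclass at MAF 0.5 (pooled case MAF 0.35 in expectation, controls 0.325).
The simulation confirms the closed-form error factor in expectation and
shows the pooled allelic test has essentially no power at genome-wide
alpha, while testing the subclass against all controls is well powered.
"""

import casehet as ch

model = ch.masked_subgroup_model(seed=42)
val = ch.empirical_validation(model, replicates=10_000)
print(f"mean pooled OR      : {val.mean_pooled_or:.3f} +/- {val.se_pooled_or:.3f}")
print(f"mean error factor   : {val.mean_error_factor:.3f} +/- {val.se_error_factor:.3f}")
print(f"closed-form factor  : {val.expected_error_factor:.3f}")
print(f"bias                : {val.bias:+.4f}")

pw = ch.power_estimate(model, alpha=5e-8, replicates=10_000)
print(f"\npower at alpha=5e-8 : pooled {pw.power_pooled:.3f}  "
      f"subgroup-only {pw.power_subgroup:.3f}")
print("\nThe pooled test virtually never reaches genome-wide significance —")
print("the subgroup-driven SNP is lost to type II error unless the subclass")
print("is analysed directly.")
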