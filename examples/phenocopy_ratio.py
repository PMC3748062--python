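"""Chi-square recovered by reclassifying phenocopies as controls.

If a proportion sigma of cases are phenocopies (control-like allele
frequencies), moving them to the control group multiplies the chi-square
statistic by [(c+d)+sigma(a+b)] / [(1-sigma)(c+d)] — (1+sigma)/(1-sigma)
for equal-sized groups.  Two clinical shares illustrate the stakes: ~15%
thymomatous myasthenia gravis, and ~40% ACPA-negative rheumatoid arthritis.
"""

import casehet as ch

table = ch.AlleleTable(700, 1300, 650, 1350)

rec = ch.phenocopy_adjustment(table, sigma=0.2)
print(f"original chi2 : {rec.chi2_original:.3f}")
print(f"adjusted table: {rec.adjusted}")
print(f"new chi2      : {rec.chi2_new:.3f}  (ratio {rec.ratio:.2f}, closed form "
      f"{ch.chi2_ratio_general(table, 0.2):.2f})")
print()
print(f"equal-n ratio at sigma=0.15 (MG thymoma share)  : {ch.chi2_ratio_equal_n(0.15):.2f}")
print(f"equal-n ratio at sigma=0.40 (ACPA- RA share)    : {ch.chi2_ratio_equal_n(0.40):.2f}")
print()
print("A 20% phenocopy share hides a third of the chi-square; at 40% the")
print("unstratified statistic is under half of what stratification recovers.")
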