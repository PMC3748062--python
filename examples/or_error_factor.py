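"""How a hidden case subclass attenuates the observed odds ratio.

A cohort of 1000 cases / 1000 controls shows a weak allelic association
(case MAF 0.35 vs control MAF 0.325).  If the signal actually comes from a
200-case subclass at MAF 0.5, the subclass's true OR is much larger than
the pooled one, by the closed-form error factor (a1/a)/(b1/b).
"""

import casehet as ch

table = ch.AlleleTable(700, 1300, 650, 1350)
sub = ch.SubclassCounts(200, 200)

pooled = ch.assoc_stats(table)
print(f"pooled OR        : {pooled.odds_ratio:.2f}   (p = {pooled.p_value:.3g})")
print(f"subclass OR      : {ch.subgroup_true_or(table, sub):.2f}")
print(f"error factor     : {ch.or_error_factor_counts(table, sub):.2f}")
print(f"from MAFs alone  : {ch.or_error_factor_mafs(0.35, 0.50):.2f}")
print()
print("The pooled analysis understates the subclass's effect ~1.9-fold;")
print("the frequency form shows the factor depends only on the two MAFs,")
print("not on the subclass size.")
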