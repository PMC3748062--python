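"""Attenuation grid: OR and p as heterogeneity dilutes a subgroup signal.

Controls sit at MAF 38%; a fully penetrant-subgroup cohort has cases at 30%.
As the fraction h of cases with control-like frequencies grows, the pooled
case MAF drifts to (1-h)*0.30 + h*0.38 and a genome-wide-significant signal
decays to noise.
"""

import casehet as ch

rows = ch.het_scan(1000, 1000, q_subgroup=0.30, p_control=0.38,
                   h_grid=[i / 10 for i in range(10)])
print(f"{'het':>4} {'case MAF':>9} {'case a1':>8} {'OR':>5} {'p':>10}")
for r in rows:
    print(f"{r.het:4.1f} {r.case_maf:9.3f} {r.case_a1:8.0f} "
          f"{r.or_value:5.2f} {r.p_value:10.3g}")
print()
print("At h=0 the association is borderline genome-wide significant")
print("(p ~ 9e-8); by h=0.5 it is three orders of magnitude weaker, and")
print("beyond h=0.7 it would not survive even a single-SNP test.")
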