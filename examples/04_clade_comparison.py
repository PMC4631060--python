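"""Reproduce the coliphage clade A vs clade B comparison from the bundled
per-phage tables.

Clade A: 8 virulent podophages; clade B: 16 temperate lambdoid phages.
The battery: Welch and pooled t plus a variance-ratio F on P_SD, pooled
t on M_SD and both MFE windows, and the SD-vs-structure correlation
panel across all 24 genomes.
"""

from phagetir import compare_groups
from phagetir.datasets import coliphage_summary_table

df = coliphage_summary_table()
report = compare_groups(df, "clade")

print(f"groups: A n={report.n['A']}, B n={report.n['B']}\n")
print("unweighted group means:")
print(report.means.round(4).to_string())
print(f"\ngene-weighted pooled P_SD: A = {report.pooled_p_sd['A']:.2f} %, "
      f"B = {report.pooled_p_sd['B']:.2f} %")

print("\ntwo-group tests (two-tailed):")
for name, t in report.tests.items():
    print(f"  {name:<18} {t.variant:<8} statistic = {t.statistic:8.4f}  "
          f"d.f. = {str(t.df_reported):<8} P = {t.p_value:.3g}")

print("\nSD features vs folding stability (positive r: strong SD goes with")
print("weak structure, i.e. coordinated selection on initiation efficiency):")
for name, (r, t) in report.correlations.items():
    print(f"  {name:<22} r = {r:+.4f}  P = {t.p_value:.3g}")
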