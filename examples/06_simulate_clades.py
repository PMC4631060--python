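"""Closed-loop check: simulate two clades, run the full pipeline, and see
the planted contrasts come back out.

Clade A (virulent-like): P_SD 0.94, SD lengths averaging 5.9 nt, AU-rich
flanks, strong codon selection.  Clade B (temperate-like): P_SD 0.68,
SD lengths averaging 5.0 nt, GC-rich flanks, weak selection.
"""

from phagetir import HostReference, E_COLI_TAIL, codon_counts, compare_groups, summarize
from phagetir.synthetic_data import default_true_weights, simulate_two_clades

genomes, metadata, truth = simulate_two_clades(seed=11)
host = HostReference(tail=E_COLI_TAIL, heg_counts=codon_counts("AUGAAAUAA"),
                     background_freqs={n: 0.25 for n in "ACGU"}, w=default_true_weights())

summaries = summarize(genomes, host, metadata=metadata)
print(summaries[["phage", "n_cds", "p_sd", "m_sd", "mfe_40nt", "mfe_m4p37", "mean_i_te", "clade"]]
      .round(3).to_string(index=False))

report = compare_groups(summaries, "clade")
print("\nrecovered contrasts (A - B, two-tailed):")
for name, t in report.tests.items():
    print(f"  {name:<18} statistic = {t.statistic:8.4f}  d.f. = {str(t.df_reported):<8} "
          f"P = {t.p_value:.3g}")
print("\nall planted directions (higher P_SD/M_SD/I_TE, weaker folding in clade A)")
print("should be significant at conventional levels")
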