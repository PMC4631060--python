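"""Published per-phage summary tables bundled as example inputs.

Two small, widely reproduced per-genome tables for 24 E. coli dsDNA
phages (8 in clade A, all virulent podophages; 16 lambdoid phages in
clade B, all temperate): SD features (P_SD percent of SD-containing
genes, M_SD mean SD-aSD duplex length) and folding stability of the two
initiation windows (MFE_40nt, MFE_-4+37).  Also the host-genome SD
proportions used for the E. coli vs S. aureus contrast.  These are
inputs for the comparison stage and the worked examples; the pipeline
can recompute such tables from annotated genome files.
"""

from __future__ import annotations

import pandas as pd

# phage, accession, n_cds, p_sd, m_sd
_SD_ROWS = [
    ("T7", "NC_001604", 60, 96.670, 5.879, "A"),
    ("T3", "NC_003298", 55, 90.910, 6.020, "A"),
    ("K1F", "NC_007456", 43, 88.370, 5.921, "A"),
    ("K1E", "NC_007637", 62, 95.160, 5.763, "A"),
    ("K1-5", "NC_008152", 52, 96.150, 5.600, "A"),
    ("BA14", "NC_011040", 52, 94.230, 5.878, "A"),
    ("EcoDS1", "NC_011042", 53, 94.340, 6.140, "A"),
    ("13a", "NC_011045", 55, 96.360, 5.943, "A"),
    ("VT2-Sakai", "NC_000902", 83, 62.650, 5.000, "B"),
    ("933W", "NC_000924", 80, 70.000, 5.036, "B"),
    ("lambda", "NC_001416", 73, 69.860, 4.922, "B"),
    ("N15", "NC_001901", 60, 80.000, 5.000, "B"),
    ("HK022", "NC_002166", 57, 56.140, 4.875, "B"),
    ("HK97", "NC_002167", 61, 68.850, 5.024, "B"),
    ("phiP27", "NC_003356", 58, 67.240, 5.359, "B"),
    ("SFV", "NC_003444", 53, 69.810, 4.676, "B"),
    ("Stx2-I", "NC_003525", 166, 47.590, 4.873, "B"),
    ("BP-4795", "NC_004813", 85, 63.530, 5.019, "B"),
    ("Stx1", "NC_004913", 84, 80.950, 5.162, "B"),
    ("Stx2-II", "NC_004914", 89, 75.280, 5.239, "B"),
    ("Stx2-86", "NC_008464", 81, 74.070, 5.150, "B"),
    ("cdtI", "NC_009514", 60, 71.670, 4.977, "B"),
    ("Min27", "NC_010237", 83, 71.080, 4.915, "B"),
    ("Stx2-1717", "NC_011357", 77, 63.640, 5.082, "B"),
]

# phage, accession, n_cds, mfe_40nt, mfe_m4p37
_MFE_ROWS = [
    ("13a", "NC_011045", 55, -5.3735, -4.7076, "A"),
    ("EcoDS1", "NC_011042", 53, -5.5532, -5.6291, "A"),
    ("K1-5", "NC_008152", 52, -5.2631, -3.8735, "A"),
    ("K1E", "NC_007637", 62, -4.8619, -4.1960, "A"),
    ("K1F", "NC_007456", 43, -5.8679, -6.5579, "A"),
    ("T3", "NC_003298", 55, -5.1473, -4.6391, "A"),
    ("T7", "NC_001604", 60, -5.0047, -4.2622, "A"),
    ("BA14", "NC_011040", 52, -4.3469, -4.2873, "A"),
    ("phiP27", "NC_003356", 58, -5.7564, -5.2038, "B"),
    ("SFV", "NC_003444", 53, -6.5808, -6.0811, "B"),
    ("933W", "NC_000924", 80, -6.2833, -6.4413, "B"),
    ("Min27", "NC_010237", 83, -6.4707, -6.0010, "B"),
    ("VT2-Sakai", "NC_000902", 83, -5.9863, -6.2927, "B"),
    ("Stx2-I", "NC_003525", 166, -6.4645, -6.6228, "B"),
    ("BP-4795", "NC_004813", 85, -7.0353, -5.9579, "B"),
    ("cdtI", "NC_009514", 60, -7.0232, -6.1000, "B"),
    ("HK022", "NC_002166", 57, -6.2793, -4.6179, "B"),
    ("HK97", "NC_002167", 61, -6.6669, -4.7044, "B"),
    ("lambda", "NC_001416", 73, -6.9789, -5.7668, "B"),
    ("N15", "NC_001901", 60, -7.0329, -5.6890, "B"),
    ("Stx1", "NC_004913", 84, -6.0289, -5.6139, "B"),
    ("Stx2-II", "NC_004914", 89, -6.3666, -5.9200, "B"),
    ("Stx2-1717", "NC_011357", 77, -6.6052, -5.8212, "B"),
    ("Stx2-86", "NC_008464", 81, -5.8188, -5.5885, "B"),
]

#: host-genome SD-containing gene proportions: species -> (n_genes, proportion)
HOST_SD_PROPORTIONS = {"S_aureus": (2767, 0.9256), "E_coli": (4321, 0.8287)}


def coliphage_sd_table() -> pd.DataFrame:
    """Per-phage SD features (P_SD, M_SD) for the 24 coliphages, with clade labels."""
    df = pd.DataFrame(_SD_ROWS, columns=["phage", "accession", "n_cds", "p_sd", "m_sd", "clade"])
    df["lifestyle"] = df["clade"].map({"A": "virulent", "B": "temperate"})
    return df


def coliphage_mfe_table() -> pd.DataFrame:
    """Per-phage folding stability (MFE_40nt, MFE_-4+37) for the same 24 phages."""
    df = pd.DataFrame(_MFE_ROWS, columns=["phage", "accession", "n_cds", "mfe_40nt", "mfe_m4p37", "clade"])
    df["lifestyle"] = df["clade"].map({"A": "virulent", "B": "temperate"})
    return df


def coliphage_summary_table() -> pd.DataFrame:
    """SD and MFE tables merged into one per-genome summary, sorted by accession."""
    sd = coliphage_sd_table()
    mfe = coliphage_mfe_table()[["accession", "mfe_40nt", "mfe_m4p37"]]
    return sd.merge(mfe, on="accession").sort_values("accession").reset_index(drop=True)
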