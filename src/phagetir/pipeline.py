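"""End-to-end orchestration: per-genome summaries and group comparisons.

``summarize`` turns annotated genomes into one row per genome (P_SD,
M_SD, mean MFE of both windows, mean I_TE); ``compare_groups`` runs the
full battery of two-group tests and the SD-vs-structure correlation
panel, optionally repeating the correlations on phylogenetically
independent contrasts when a tree is supplied.  All group statistics are
computed on per-genome values (n = genomes), never per-gene values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import codon_adapt, mfe_fold, sd_detect, seq_io, stats


@dataclass
class PipelineConfig:
    tail: sd_detect.AntiSDTail = sd_detect.E_COLI_TAIL
    sd_cfg: sd_detect.SDCallConfig = field(default_factory=sd_detect.SDCallConfig)
    fold_settings: mfe_fold.FoldSettings = field(default_factory=mfe_fold.FoldSettings)
    min_codons: int = 33


SUMMARY_COLUMNS = ["phage", "accession", "n_cds", "p_sd", "m_sd",
                   "mfe_40nt", "mfe_m4p37", "mean_i_te", "lifestyle", "clade"]


def summarize(genomes: list[seq_io.GenomeAnnotation],
              host_ref: codon_adapt.HostReference | None = None,
              cfg: PipelineConfig | None = None,
              metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """One summary row per genome, ordered by accession.

    ``metadata`` (columns genome_id, clade, lifestyle) attaches the
    externally supplied labels; they are never inferred from sequence.
    Mean I_TE is only computed when a host reference is given.
    """
    if not genomes:
        raise ValueError("empty genome set")
    cfg = cfg or PipelineConfig()
    meta_idx = metadata.set_index("genome_id") if metadata is not None else None
    rows = []
    for genome in genomes:
        genes = seq_io.filter_min_codons(seq_io.build_gene_records(genome), cfg.min_codons)
        if not genes:
            raise ValueError(f"genome {genome.genome_id}: no genes pass the length filter")
        sd = sd_detect.genome_sd_summary(genes, cfg.tail, cfg.sd_cfg)
        m40, mflank = mfe_fold.genome_mfe_summary(genes, cfg.fold_settings)
        mean_ite = None
        if host_ref is not None:
            scores = [codon_adapt.ite(codon_adapt.codon_counts(g.cds_seq), host_ref.w) for g in genes]
            mean_ite = float(np.mean(scores))
        lifestyle = clade = None
        if meta_idx is not None and genome.genome_id in meta_idx.index:
            lifestyle = meta_idx.loc[genome.genome_id].get("lifestyle")
            clade = meta_idx.loc[genome.genome_id].get("clade")
        rows.append({"phage": genome.genome_id, "accession": genome.genome_id,
                     "n_cds": len(genes), "p_sd": sd.p_sd, "m_sd": sd.m_sd,
                     "mfe_40nt": m40, "mfe_m4p37": mflank, "mean_i_te": mean_ite,
                     "lifestyle": lifestyle, "clade": clade})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS).sort_values("accession").reset_index(drop=True)


def write_summaries(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, sep="\t", index=False)


def read_summaries(path) -> pd.DataFrame:
    """Read a summary TSV back bit-identically (round-trip float parsing)."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


@dataclass
class ComparisonReport:
    group_field: str
    groups: tuple[str, str]
    n: dict[str, int]
    means: pd.DataFrame  # unweighted per-group means of each metric
    variances: pd.DataFrame
    pooled_p_sd: dict[str, float] | None  # gene-weighted pooled P_SD per group
    tests: dict[str, stats.TestResult]
    correlations: dict[str, tuple[float, stats.TestResult]]
    pic_correlations: dict[str, tuple[float, stats.TestResult]] | None = None

    def to_markdown(self) -> str:
        lines = [f"## Group comparison by `{self.group_field}` "
                 f"({self.groups[0]}: n={self.n[self.groups[0]]}, {self.groups[1]}: n={self.n[self.groups[1]]})", ""]
        lines.append(self.means.round(4).to_markdown())
        lines.append("")
        lines.append("| test | statistic | d.f. | P |")
        lines.append("|---|---|---|---|")
        for name, t in self.tests.items():
            lines.append(f"| {name} ({t.variant}) | {t.statistic:.4f} | {t.df_reported} | {t.p_value:.4g} |")
        for label, panel in (("Pearson", self.correlations), ("PIC", self.pic_correlations or {})):
            for name, (r, t) in panel.items():
                lines.append(f"| {label} {name} | r = {r:.4f} | {t.df_reported} | {t.p_value:.4g} |")
        return "\n".join(lines)


_METRICS = ["p_sd", "m_sd", "mfe_40nt", "mfe_m4p37", "mean_i_te"]


def compare_groups(summaries: pd.DataFrame, group_field: str = "clade",
                   tree: "dendropy.Tree | str | None" = None,
                   tip_field: str = "phage") -> ComparisonReport:
    """Two-group comparison over per-genome summaries.

    Runs, where the metric is present: Welch and pooled t plus the
    variance-ratio F on P_SD; pooled t on M_SD, MFE_40nt, MFE_-4+37 and
    mean I_TE; and the SD-vs-structure correlation panel across all
    genomes, raw and (when a tree with matching tip labels is given) on
    independent contrasts.
    """
    df = summaries.dropna(subset=[group_field]) if group_field in summaries else summaries
    groups = sorted(df[group_field].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups in {group_field!r}, got {groups}")
    a = df[df[group_field] == groups[0]]
    b = df[df[group_field] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 genomes to compare")

    present = [m for m in _METRICS if m in df.columns and df[m].notna().all()]
    means = pd.DataFrame({g: sub[present].mean() for g, sub in ((groups[0], a), (groups[1], b))}).T
    variances = pd.DataFrame({g: sub[present].var(ddof=1) for g, sub in ((groups[0], a), (groups[1], b))}).T

    tests: dict[str, stats.TestResult] = {}
    if "p_sd" in present:
        tests["p_sd_welch"] = stats.welch_t(a["p_sd"], b["p_sd"])
        tests["p_sd_pooled"] = stats.pooled_t(a["p_sd"], b["p_sd"])
        tests["p_sd_f_var"] = stats.f_var(a["p_sd"], b["p_sd"])
    for metric in ("m_sd", "mfe_40nt", "mfe_m4p37", "mean_i_te"):
        if metric in present:
            tests[f"{metric}_pooled"] = stats.pooled_t(a[metric], b[metric])

    pooled = None
    if "p_sd" in present and "n_cds" in df.columns:
        pooled = {g: float(100 * (sub["n_cds"] * sub["p_sd"] / 100).sum() / sub["n_cds"].sum())
                  for g, sub in ((groups[0], a), (groups[1], b))}

    correlations: dict[str, tuple[float, stats.TestResult]] = {}
    for sd_metric in ("p_sd", "m_sd"):
        for mfe_metric in ("mfe_40nt", "mfe_m4p37"):
            if sd_metric in present and mfe_metric in present:
                correlations[f"{sd_metric}_vs_{mfe_metric}"] = stats.pearson(df[sd_metric], df[mfe_metric])

    pic_correlations = None
    if tree is not None:
        pic_correlations = {}
        for key in list(correlations):
            sd_metric, mfe_metric = key.split("_vs_")
            x = dict(zip(df[tip_field], df[sd_metric]))
            y = dict(zip(df[tip_field], df[mfe_metric]))
            cs = stats.pic(tree, x, y)
            pic_correlations[key] = (cs.r, cs.test)

    return ComparisonReport(group_field, (groups[0], groups[1]),
                            {groups[0]: len(a), groups[1]: len(b)},
                            means, variances, pooled, tests, correlations, pic_correlations)
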