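"""Codon-usage adaptation: RSCU, mutation-bias-corrected weights, and I_TE.

RSCU_i is the observed count of codon i divided by its expected count
under uniform synonym usage within its family.  The index of translation
elongation, I_TE, is a CAI-like geometric mean of per-codon weights w_i,
but the weights are derived from a host highly-expressed-gene (HEG) set
*after* discounting background mutation bias: within each synonymous
subfamily the expected usage E_i of codon i is its third-position
nucleotide's background frequency renormalised over the subfamily, and

    raw_i = P_i / E_i,        w_i = raw_i / max(raw within subfamily),

so w_i = 1 marks the codon most enriched relative to mutation pressure,
not merely the most common one.  Synonymous families are partitioned by
"method 2": the sixfold Leu/Ser/Arg families are broken into their
fourfold and twofold subfamilies (CUN+UUR, UCN+AGY, CGN+AGR), because the
two blocks differ at non-third positions and are not free to interchange
by third-position substitution.  Classical CAI weights (relative
adaptiveness from the same HEG set, no mutation-bias correction) are
provided as a comparator.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from . import stats as _stats
from .sd_detect import AntiSDTail
from .seq_io import to_rna

_STANDARD = CodonTable.unambiguous_rna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))  # 61 codons
AMINO_ACID = dict(_STANDARD.forward_table)

# method-2 subfamily splits of the sixfold families
_SIXFOLD_SPLIT = {
    "L": (("CUU", "CUC", "CUA", "CUG"), ("UUA", "UUG")),
    "S": (("UCU", "UCC", "UCA", "UCG"), ("AGU", "AGC")),
    "R": (("CGU", "CGC", "CGA", "CGG"), ("AGA", "AGG")),
}


def family_split(method: int = 2) -> list[tuple[str, ...]]:
    """Partition of the 61 sense codons into synonymous (sub)families.

    method 1: one family per amino acid.  method 2: sixfold families split
    into fourfold + twofold subfamilies.  Methods 3-4 are not implemented.
    """
    if method not in (1, 2):
        raise ValueError(f"unknown family-split method {method!r} (supported: 1, 2)")
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(AMINO_ACID[codon], []).append(codon)
    families: list[tuple[str, ...]] = []
    for aa, codons in sorted(by_aa.items()):
        if method == 2 and aa in _SIXFOLD_SPLIT:
            families.extend(tuple(c) for c in _SIXFOLD_SPLIT[aa])
        else:
            families.append(tuple(sorted(codons)))
    return families


@dataclass
class CodonCounts:
    """Sense-codon counts over a gene or gene set (stops tracked separately)."""

    counts: dict[str, int] = field(default_factory=dict)
    stop_counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(dict(Counter(self.counts) + Counter(other.counts)),
                           dict(Counter(self.stop_counts) + Counter(other.stop_counts)))


def codon_counts(cds: str | Iterable[str], exclude_start: bool = True) -> CodonCounts:
    """Count codons of one CDS or a collection of CDSs (RNA or DNA input).

    The start codon is excluded by default (it is fixed AUG and carries no
    usage signal); codons with ambiguity codes are skipped.
    """
    if not isinstance(cds, str):
        out = CodonCounts()
        for seq in cds:
            out = out + codon_counts(seq, exclude_start=exclude_start)
        return out
    seq = to_rna(cds)
    counts: Counter = Counter()
    stops: Counter = Counter()
    start = 3 if exclude_start else 0
    for i in range(start, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            stops[codon] += 1
        elif codon in AMINO_ACID:
            counts[codon] += 1
    return CodonCounts(dict(counts), dict(stops))


def rscu(counts: CodonCounts, method: int = 1) -> dict[str, float]:
    """Relative synonymous codon usage; families with zero total give NaN."""
    if counts.total() == 0:
        raise ValueError("empty codon counts")
    out: dict[str, float] = {}
    for family in family_split(method):
        if len(family) == 1:
            continue  # Met/Trp carry no synonymous signal
        total = sum(counts[c] for c in family)
        for c in family:
            out[c] = len(family) * counts[c] / total if total else math.nan
    return out


def third_position_freqs(cds_seqs: Iterable[str]) -> dict[str, float]:
    """Background nucleotide proportions at codon third positions.

    Used as the mutation-bias proxy when deriving host codon weights.
    """
    counter: Counter = Counter()
    for seq in cds_seqs:
        s = to_rna(seq)
        counter.update(s[i + 2] for i in range(0, len(s) - len(s) % 3, 3) if s[i + 2] in "ACGU")
    total = sum(counter.values())
    if total == 0:
        raise ValueError("no unambiguous third positions")
    return {nt: counter[nt] / total for nt in "ACGU"}


def host_weights(heg_counts: CodonCounts, background_freqs: Mapping[str, float],
                 method: int = 2, pseudo_count: float = 0.5) -> dict[str, float]:
    """Mutation-bias-corrected relative adaptiveness w_i from a HEG set.

    Within each subfamily: E_i = background frequency of the codon's third
    nucleotide renormalised over the subfamily; raw_i = P_i / E_i;
    w_i = raw_i / max(raw).  Unobserved codons are floored at
    ``pseudo_count`` so a missing codon cannot zero out a geometric mean.
    Single-codon families (Met, Trp) have no defined w.  Subfamilies with
    no HEG observations at all are left out (flagged by absence).
    """
    w: dict[str, float] = {}
    for family in family_split(method):
        if len(family) == 1:
            continue
        obs = np.array([heg_counts[c] for c in family], float)
        if obs.sum() == 0:
            continue
        obs = np.where(obs == 0, pseudo_count, obs)
        p = obs / obs.sum()
        e = np.array([background_freqs[c[2]] for c in family], float)
        if e.sum() == 0:
            raise ValueError(f"background frequencies degenerate for family {family}")
        e = e / e.sum()
        raw = p / e
        for c, val in zip(family, raw / raw.max()):
            w[c] = float(val)
    return w


def cai_weights(heg_counts: CodonCounts, method: int = 1, pseudo_count: float = 0.5) -> dict[str, float]:
    """Classical relative adaptiveness (RSCU_i / RSCU_max), uncorrected."""
    uniform = {nt: 0.25 for nt in "ACGU"}
    return host_weights(heg_counts, uniform, method=method, pseudo_count=pseudo_count)


def _geometric_mean_score(gene_counts: CodonCounts, w: Mapping[str, float]) -> tuple[float, int]:
    log_sum, n = 0.0, 0
    for codon, count in gene_counts.counts.items():
        wi = w.get(codon)
        if wi is None or count == 0:
            continue
        if wi <= 0:
            raise ValueError(f"non-positive weight for {codon}")
        log_sum += count * math.log(wi)
        n += count
    if n == 0:
        raise ValueError("gene has no codons with defined weights")
    return math.exp(log_sum / n), n


def ite(gene_counts: CodonCounts, w: Mapping[str, float]) -> float:
    """Index of translation elongation: geometric mean of w over scorable codons."""
    return _geometric_mean_score(gene_counts, w)[0]


def cai(gene_counts: CodonCounts, w_cai: Mapping[str, float]) -> float:
    """Codon adaptation index under classical (uncorrected) weights."""
    return _geometric_mean_score(gene_counts, w_cai)[0]


@dataclass
class HostReference:
    """Everything the pipeline needs to know about the host.

    ``w`` is derived from the HEG counts and background frequencies on
    construction when not supplied.
    """

    tail: AntiSDTail
    heg_counts: CodonCounts
    background_freqs: dict[str, float]
    w: dict[str, float] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.w:
            self.w = host_weights(self.heg_counts, self.background_freqs)

    @classmethod
    def from_heg_fasta(cls, tail: AntiSDTail, heg_cds: Sequence[str],
                       background_cds: Sequence[str] | None = None, source: str = "") -> "HostReference":
        bg = third_position_freqs(background_cds if background_cds is not None else heg_cds)
        return cls(tail=tail, heg_counts=codon_counts(heg_cds), background_freqs=bg, source=source)


def r_rscu(phage_counts: CodonCounts, host_ref: HostReference,
           host_all_counts: CodonCounts | None = None,
           variant: str = "w_based") -> tuple[float, "_stats.TestResult"]:
    """Pearson correlation between phage RSCU and a host usage vector.

    variant 'all_genes' correlates against RSCU of the whole host gene set
    (strongly mutation-bias-confounded), 'heg' against RSCU of the host
    HEG set, and 'w_based' against the mutation-bias-corrected w vector.
    Codons missing on either side are pairwise-deleted.
    """
    phage = rscu(phage_counts)
    if variant == "all_genes":
        if host_all_counts is None:
            raise ValueError("variant 'all_genes' needs host_all_counts")
        host = rscu(host_all_counts)
    elif variant == "heg":
        host = rscu(host_ref.heg_counts)
    elif variant == "w_based":
        host = dict(host_ref.w)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    shared = [c for c in phage if c in host
              and not (math.isnan(phage[c]) or math.isnan(host[c]))]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared informative codons")
    return _stats.pearson([phage[c] for c in shared], [host[c] for c in shared])
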