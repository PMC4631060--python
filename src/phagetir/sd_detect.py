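"""Shine-Dalgarno detection by pairing against the SSU rRNA 3' tail.

A Shine-Dalgarno (SD) element is located by searching the 30 nt upstream
of the start codon for maximal, perfect, antiparallel Watson-Crick
duplexes with the free 3' tail of the small-subunit rRNA (13 nt in
E. coli).  The positional quality of a duplex is measured by D_toAUG, the
distance in nt from the rRNA 3' terminus to the first base of the start
codon when the duplex is formed:

    D_toAUG = tail_overhang + L + spacer

where L is the duplex length, ``spacer`` the nt between the SD 3' end and
the start codon, and ``tail_overhang`` the tail nt 3' of the matched
segment.  A gene "has an SD" when some duplex of length >= 4 yields a
D_toAUG inside the configured window (10..20 by default, where the
empirical D_toAUG distribution is concentrated, with its mode at 13).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seq_io import GeneRecord, is_unambiguous, to_rna

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

OPTIMAL_D_TOAUG = 13


@dataclass(frozen=True)
class AntiSDTail:
    """Free 3'-terminal segment of the SSU rRNA, 5'->3' (last base = 3' terminus)."""

    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        if len(self.sequence) < 4:
            raise ValueError("anti-SD tail must be at least 4 nt")

    def __len__(self) -> int:
        return len(self.sequence)


#: Canonical 13-nt free 3' tail of the E. coli 16S rRNA.
E_COLI_TAIL = AntiSDTail("GAUCACCUCCUUA", source="E. coli 16S rRNA 3' terminus")


@dataclass(frozen=True)
class SDMatch:
    """One maximal SD-aSD duplex.

    Positions are 1-based: ``mrna_start``/``mrna_end`` within the upstream
    sequence (1 = its 5'-most base), ``tail_start``/``tail_end`` within the
    tail (5'->3').
    """

    gene_id: str
    mrna_start: int
    mrna_end: int
    tail_start: int
    tail_end: int
    L: int
    spacer: int
    tail_overhang: int
    d_toaug: int


@dataclass(frozen=True)
class SDCallConfig:
    min_len: int = 4
    d_window: tuple[int, int] | None = (10, 20)  # None: position-free (any hit in the upstream)
    upstream_len: int = 30

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.d_window is not None and (self.d_window[0] < 1 or self.d_window[0] > self.d_window[1]):
            raise ValueError("invalid d_window")


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def find_matches(upstream: str, tail: AntiSDTail, min_len: int = 4, gene_id: str = "") -> list[SDMatch]:
    """All maximal antiparallel perfect Watson-Crick duplexes of length >= min_len.

    A maximal duplex (one that cannot be extended on either side) is
    reported once, never again as its nested sub-duplexes.  Non-ACGU
    characters never pair.
    """
    u = to_rna(upstream)
    t = tail.sequence
    U, T = len(u), len(t)
    out: list[SDMatch] = []
    # Antiparallel pairing: upstream pos a pairs tail pos b, and extending the
    # duplex 3' on the mRNA moves 5' on the tail, so a+b is constant along a
    # duplex. Scan each anti-diagonal for maximal runs of paired sites.
    for c in range(2, U + T + 1):
        a_lo, a_hi = max(1, c - T), min(U, c - 1)
        run = 0
        for a in range(a_lo, a_hi + 2):
            ok = a <= a_hi and _pairs(u[a - 1], t[c - a - 1])
            if ok:
                run += 1
            else:
                if run >= min_len:
                    a_end = a - 1  # last paired mRNA position
                    a_start = a_end - run + 1
                    tail_end = c - a_start
                    tail_start = c - a_end
                    spacer = U - a_end
                    overhang = T - tail_end
                    out.append(
                        SDMatch(gene_id, a_start, a_end, tail_start, tail_end, run,
                                spacer, overhang, overhang + run + spacer)
                    )
                run = 0
    out.sort(key=lambda m: (m.mrna_start, m.tail_start))
    return out


def call_sd(matches: Sequence[SDMatch], cfg: SDCallConfig = SDCallConfig()) -> tuple[bool, SDMatch | None]:
    """Apply the operational SD definition; return (has_sd, best qualifying match).

    Best = longest duplex; ties broken by D_toAUG closest to 13, then by the
    5'-most position in the upstream.
    """
    qualifying = [m for m in matches if m.L >= cfg.min_len]
    if cfg.d_window is not None:
        lo, hi = cfg.d_window
        qualifying = [m for m in qualifying if lo <= m.d_toaug <= hi]
    if not qualifying:
        return False, None
    best = min(qualifying, key=lambda m: (-m.L, abs(m.d_toaug - OPTIMAL_D_TOAUG), m.mrna_start))
    return True, best


@dataclass(frozen=True)
class SDSummary:
    p_sd: float  # percent of genes with a qualifying SD
    m_sd: float | None  # mean best-duplex length over SD-containing genes
    n_genes: int
    n_sd: int


def gene_upstream(gene: GeneRecord, cfg: SDCallConfig) -> str | None:
    """SD search space for one gene; None when unusable (ambiguous/short)."""
    if cfg.upstream_len == 30:
        up = gene.upstream30
    elif cfg.upstream_len <= 40:
        up = gene.upstream40[-cfg.upstream_len:]
    else:
        raise ValueError("upstream_len beyond the extracted 40-nt window")
    if len(up) < cfg.upstream_len or not is_unambiguous(up):
        return None
    return up


def genome_sd_summary(genes: Iterable[GeneRecord], tail: AntiSDTail = E_COLI_TAIL,
                      cfg: SDCallConfig = SDCallConfig()) -> SDSummary:
    """Per-genome P_SD (percent SD-containing genes) and M_SD (mean duplex length).

    Genes whose upstream window is truncated or carries ambiguity codes are
    excluded from both numerator and denominator.
    """
    n = n_sd = 0
    lengths: list[int] = []
    for gene in genes:
        up = gene_upstream(gene, cfg)
        if up is None:
            continue
        n += 1
        has, best = call_sd(find_matches(up, tail, cfg.min_len, gene.gene_id), cfg)
        if has:
            n_sd += 1
            lengths.append(best.L)
    if n == 0:
        raise ValueError("no usable genes for SD summary")
    m_sd = float(np.mean(lengths)) if lengths else None
    return SDSummary(p_sd=100.0 * n_sd / n, m_sd=m_sd, n_genes=n, n_sd=n_sd)


def all_matches(genes: Iterable[GeneRecord], tail: AntiSDTail = E_COLI_TAIL,
                min_len: int = 4, upstream_len: int = 30) -> list[SDMatch]:
    """Every maximal duplex across genes, position-free (for histograms)."""
    cfg = SDCallConfig(min_len=min_len, d_window=None, upstream_len=upstream_len)
    out: list[SDMatch] = []
    for gene in genes:
        up = gene_upstream(gene, cfg)
        if up is not None:
            out.extend(find_matches(up, tail, min_len, gene.gene_id))
    return out


def dtoaug_histogram(matches: Iterable[SDMatch]) -> dict[int, int]:
    """Frequency distribution of D_toAUG over all matches (not best-per-gene)."""
    return dict(sorted(Counter(m.d_toaug for m in matches).items()))


def tail_participation(matches: Iterable[SDMatch], tail_len: int = 13) -> np.ndarray:
    """How often each tail site (1..tail_len, 5'->3') is inside a duplex."""
    counts = np.zeros(tail_len, dtype=int)
    for m in matches:
        counts[m.tail_start - 1 : m.tail_end] += 1
    return counts
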