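"""Minimum-folding-energy of the two initiation-region windows.

Secondary structure that buries the SD element or the start codon lowers
translation-initiation efficiency, so each gene is scored by the MFE of
two windows: the 40 nt upstream of the start codon (``MFE_40nt``, SD
accessibility) and the -4..+37 window spanning the start codon
(``MFE_-4+37``, start-codon accessibility).  Folding uses the ViennaRNA
nearest-neighbor model at 37 degC with lonely pairs disallowed and no G/U
pairs closing helices.

Energies are in the engine's native kcal/mol.  More negative = more
stable; values are used comparatively, so only the relative magnitudes
matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import RNA

from . import stats as _stats
from .sd_detect import AntiSDTail, E_COLI_TAIL, SDCallConfig, call_sd, find_matches
from .seq_io import GeneRecord, is_unambiguous, to_rna


@dataclass(frozen=True)
class FoldSettings:
    temperature_c: float = 37.0
    no_lonely_pairs: bool = True
    no_gu_at_helix_ends: bool = True

    @property
    def engine_id(self) -> str:
        return f"ViennaRNA {RNA.__version__}"


DEFAULT_SETTINGS = FoldSettings()


class AmbiguousSequenceError(ValueError):
    """Window contains a non-ACGU base and cannot be folded."""


def _model(settings: FoldSettings) -> "RNA.md":
    md = RNA.md()
    md.temperature = settings.temperature_c
    md.noLP = int(settings.no_lonely_pairs)
    md.noGUclosure = int(settings.no_gu_at_helix_ends)
    return md


def fold_mfe(seq: str, settings: FoldSettings = DEFAULT_SETTINGS) -> float:
    """MFE (kcal/mol, <= 0) of one window; 0.0 when no stable structure forms."""
    rna = to_rna(seq)
    if not is_unambiguous(rna):
        raise AmbiguousSequenceError(f"cannot fold sequence with ambiguity codes: {seq!r}")
    fc = RNA.fold_compound(rna, _model(settings))
    _, mfe = fc.mfe()
    return min(float(mfe), 0.0)


@dataclass(frozen=True)
class FlankStructure:
    gene_id: str
    mfe_40nt: float | None
    mfe_m4p37: float | None


def _foldable(window: str, nominal_len: int) -> bool:
    return len(window) == nominal_len and is_unambiguous(window)


def flank_structures(genes: Iterable[GeneRecord], settings: FoldSettings = DEFAULT_SETTINGS) -> list[FlankStructure]:
    """Per-gene MFE of both windows; truncated/ambiguous windows give None.

    Truncated windows are not folded at all: the MFE of a shorter window
    is not comparable with the full-length ones and would bias genome
    means.
    """
    out = []
    for g in genes:
        m40 = fold_mfe(g.upstream40, settings) if _foldable(g.upstream40, 40) else None
        m4p37 = fold_mfe(g.flank_m4p37, settings) if _foldable(g.flank_m4p37, 41) else None
        out.append(FlankStructure(g.gene_id, m40, m4p37))
    return out


def genome_mfe_summary(genes: Iterable[GeneRecord],
                       settings: FoldSettings = DEFAULT_SETTINGS) -> tuple[float | None, float | None]:
    """Unweighted per-gene mean (MFE_40nt, MFE_-4+37) over complete windows."""
    structs = flank_structures(genes, settings)
    v40 = [s.mfe_40nt for s in structs if s.mfe_40nt is not None]
    vfl = [s.mfe_m4p37 for s in structs if s.mfe_m4p37 is not None]
    return (float(np.mean(v40)) if v40 else None, float(np.mean(vfl)) if vfl else None)


@dataclass(frozen=True)
class SubstitutionResult:
    window: str  # 'upstream40' or 'flank_m4p37'
    mean_delta: float
    test: "_stats.TestResult"  # paired two-tailed t of delta = 0
    n: int


def _substitution_site(window: str, gene: GeneRecord, which: str, motif_len: int,
                       tail: AntiSDTail, cfg: SDCallConfig) -> int:
    """0-based start of the motif-length segment to replace.

    Uses the best SD duplex location when one lies inside the window
    (initiation elements are what the control interrogates), else the
    window's central segment.
    """
    up = gene.upstream30
    if len(up) == 30 and is_unambiguous(up):
        has, best = call_sd(find_matches(up, tail, cfg.min_len, gene.gene_id), cfg)
        if has:
            if which == "upstream40":
                start = best.mrna_start - 1 + (len(window) - 30)  # upstream30 = 3' end of upstream40
            else:
                start = None  # SD lies 5' of the -4..+37 window
            if start is not None and 0 <= start <= len(window) - motif_len:
                return start
    return (len(window) - motif_len) // 2


def sd_substitution_control(genes: Sequence[GeneRecord], motif: str = "AGGAGG",
                            settings: FoldSettings = DEFAULT_SETTINGS,
                            tail: AntiSDTail = E_COLI_TAIL,
                            cfg: SDCallConfig = SDCallConfig()) -> dict[str, SubstitutionResult]:
    """Does inserting a canonical SD motif per se change folding stability?

    For each gene and each window, a motif-length segment (the best SD
    site when present in the window, else the central one) is replaced by
    ``motif``, the window refolded, and the per-gene delta-MFE collected;
    a paired two-tailed t-test asks whether the mean delta differs from 0.
    """
    motif = to_rna(motif)
    results = {}
    for which, nominal in (("upstream40", 40), ("flank_m4p37", 41)):
        before, after = [], []
        for g in genes:
            window = getattr(g, which)
            if not _foldable(window, nominal) or len(window) < len(motif):
                continue
            site = _substitution_site(window, g, which, len(motif), tail, cfg)
            substituted = window[:site] + motif + window[site + len(motif):]
            before.append(fold_mfe(window, settings))
            after.append(fold_mfe(substituted, settings))
        deltas = np.asarray(after) - np.asarray(before)
        test = _stats.paired_t(np.asarray(after), np.asarray(before))
        results[which] = SubstitutionResult(which, float(np.mean(deltas)), test, len(deltas))
    return results
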