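"""Synthetic annotated genomes with planted translation-initiation signals.

The generator emulates the statistical structure the comparative analysis
rests on, so every pipeline stage can be exercised end to end with known
ground truth:

* each gene's upstream region carries, with probability ``p_sd``, a
  planted SD element whose duplex length and D_toAUG are drawn from
  configurable distributions (D_toAUG peaked at the empirically optimal
  13 nt);
* flanking-window base composition is drawn at a configurable GC
  proportion, which monotonically controls folding stability;
* coding sequences are sampled codon-by-codon from a mixture of
  host-optimal weights and uniform synonym choice, so codon-adaptation
  indices have a known ordering.

Two "clades" with distinct parameter sets reproduce the qualitative
virulent-vs-temperate contrasts: clade A (virulent-like) has near-
universal long SDs, AU-rich (weakly folding) flanks and strong codon
selection; clade B (temperate-like) the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .codon_adapt import AMINO_ACID, family_split
from .sd_detect import AntiSDTail, E_COLI_TAIL, SDCallConfig, call_sd, find_matches
from .seq_io import GeneCoords, GenomeAnnotation, revcomp_rna, to_dna

#: weakly peaked at 13, falling toward the 10 and 20 edges
DEFAULT_D_DIST = {10: 0.02, 11: 0.05, 12: 0.12, 13: 0.35, 14: 0.16, 15: 0.10,
                  16: 0.08, 17: 0.05, 18: 0.04, 19: 0.02, 20: 0.01}


@dataclass(frozen=True)
class CladeParams:
    n_genomes: int = 8
    genes_per_genome: int = 60
    p_sd: float = 0.9
    sd_len_dist: Mapping[int, float] = field(default_factory=lambda: {4: 0.1, 5: 0.3, 6: 0.6})
    d_toaug_dist: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_D_DIST))
    flank_gc: float = 0.45
    codon_selection: float = 0.5  # 0 = uniform synonyms, 1 = fully host-optimal
    min_codons: int = 45
    max_codons: int = 75
    clean_negative: bool = True  # reject upstream backgrounds with spurious >=4-nt tail matches

    def __post_init__(self) -> None:
        if not 0 <= self.p_sd <= 1 or not 0 <= self.codon_selection <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        for dist in (self.sd_len_dist, self.d_toaug_dist):
            if abs(sum(dist.values()) - 1) > 1e-9:
                raise ValueError("distribution not normalised")


#: defaults mirroring the strong-initiation (virulent-like) clade
CLADE_A = CladeParams(n_genomes=8, genes_per_genome=60, p_sd=0.94,
                      sd_len_dist={5: 0.1, 6: 0.9}, flank_gc=0.35, codon_selection=0.85)
#: defaults mirroring the weak-initiation (temperate-like) clade
CLADE_B = CladeParams(n_genomes=16, genes_per_genome=60, p_sd=0.68,
                      sd_len_dist={4: 0.2, 5: 0.6, 6: 0.2}, flank_gc=0.50, codon_selection=0.25)


def default_true_weights(method: int = 2) -> dict[str, float]:
    """Deterministic ground-truth codon weights for closed-loop simulations.

    Within each subfamily (alphabetical codon order) weights fall
    geometrically 1.0, 0.6, 0.36, ... so every family has a single optimal
    codon and a known selection gradient.
    """
    w: dict[str, float] = {}
    for family in family_split(method):
        if len(family) == 1:
            continue
        for rank, codon in enumerate(sorted(family)):
            w[codon] = 0.6 ** rank
    return w


def _sample(dist: Mapping[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    return int(rng.choice(keys, p=[dist[k] for k in keys]))


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("GCAU"), size=n, p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]))


def _clean_upstream(n: int, gc: float, tail: AntiSDTail, rng: np.random.Generator,
                    max_tries: int = 500) -> str:
    """Random background whose 3'-most 30 nt contain no >=4-nt tail duplex."""
    for _ in range(max_tries):
        up = _random_bases(n, gc, rng)
        if not find_matches(up[-30:], tail, 4):
            return up
    raise RuntimeError("could not sample an SD-free background; tail too permissive?")


def _plant_sd(upstream: str, L: int, d_toaug: int, tail: AntiSDTail,
              rng: np.random.Generator) -> str | None:
    """Overwrite the upstream so its best duplex has exactly (L, d_toaug).

    The planted element pairs the tail segment ending 2 nt from the 3'
    terminus (the canonical aSD core), so spacer = d_toaug - 2 - L.
    Returns None when the resulting geometry does not fit in the 30-nt
    search space, or the plant accidentally extends into a longer duplex
    (caller resamples).
    """
    T = len(tail)
    tail_end = T - 2
    spacer = d_toaug - (T - tail_end) - L
    if spacer < 0 or spacer + L > 30:
        return None
    sd = revcomp_rna(tail.sequence[tail_end - L : tail_end])
    end = len(upstream) - spacer
    planted = upstream[: end - L] + sd + upstream[end:]
    has, best = call_sd(find_matches(planted[-30:], tail, 4), SDCallConfig(d_window=None))
    if has and best.L == L and best.d_toaug == d_toaug:
        return planted
    return None


def _sample_cds(n_codons: int, selection: float, w: Mapping[str, float],
                rng: np.random.Generator) -> str:
    families = [f for f in family_split(2)]
    codons = ["AUG"]
    for _ in range(n_codons - 2):
        fam = families[rng.integers(len(families))]
        if len(fam) == 1:
            codons.append(fam[0])
            continue
        wv = np.array([w.get(c, 1.0) for c in fam])
        probs = selection * wv / wv.sum() + (1 - selection) / len(fam)
        codons.append(fam[int(rng.choice(len(fam), p=probs / probs.sum()))])
    codons.append("UAA")
    return "".join(codons)


def simulate_genome(params: CladeParams, genome_id: str, seed: int | np.random.Generator,
                    tail: AntiSDTail = E_COLI_TAIL,
                    true_w: Mapping[str, float] | None = None) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """One linear synthetic genome plus its per-gene truth table.

    Truth columns: gene_id, planted (bool), sd_len, d_toaug (NA when not
    planted).  Layout is strictly forward-strand: each gene is preceded by
    its own 40-nt upstream block, so the extracted windows coincide with
    the generated ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = dict(true_w) if true_w is not None else default_true_weights()
    chunks: list[str] = [_random_bases(20, params.flank_gc, rng)]
    pos = 20
    genes, truth = [], []
    for i in range(params.genes_per_genome):
        gene_id = f"{genome_id}_g{i + 1:03d}"
        planted, L, D = False, None, None
        if rng.random() < params.p_sd:
            for _ in range(200):
                L = _sample(params.sd_len_dist, rng)
                D = _sample(params.d_toaug_dist, rng)
                base = (_clean_upstream(40, params.flank_gc, tail, rng)
                        if params.clean_negative else _random_bases(40, params.flank_gc, rng))
                up = _plant_sd(base, L, D, tail, rng)
                if up is not None:
                    planted = True
                    break
            else:  # pragma: no cover - geometry always resolvable for L<=6
                raise RuntimeError("could not plant SD")
        else:
            up = (_clean_upstream(40, params.flank_gc, tail, rng)
                  if params.clean_negative else _random_bases(40, params.flank_gc, rng))
            L = D = None
        n_codons = int(rng.integers(params.min_codons, params.max_codons + 1))
        cds = _sample_cds(n_codons, params.codon_selection, w, rng)
        chunks.append(up + cds)
        start = pos + 40 + 1
        genes.append(GeneCoords(gene_id, start, start + len(cds) - 1, "+"))
        truth.append({"gene_id": gene_id, "planted": planted, "sd_len": L, "d_toaug": D})
        pos += 40 + len(cds)
    genome = GenomeAnnotation(genome_id, to_dna("".join(chunks)), "linear", genes)
    return genome, pd.DataFrame(truth)


def simulate_two_clades(params_a: CladeParams = CLADE_A, params_b: CladeParams = CLADE_B,
                        seed: int = 0, tail: AntiSDTail = E_COLI_TAIL,
                        ) -> tuple[list[GenomeAnnotation], pd.DataFrame, pd.DataFrame]:
    """Two clades of genomes with contrasting initiation/codon parameters.

    Returns (genomes, metadata, truth).  Metadata maps each genome to its
    clade and a lifestyle label (clade A virulent, clade B temperate),
    mirroring how lifestyle enters the real analysis as external metadata.
    """
    rng = np.random.default_rng(seed)
    genomes, meta, truths = [], [], []
    for clade, lifestyle, params in (("A", "virulent", params_a), ("B", "temperate", params_b)):
        for i in range(params.n_genomes):
            gid = f"SIM{clade}{i + 1:02d}"
            genome, truth = simulate_genome(params, gid, rng, tail)
            genomes.append(genome)
            truth["genome_id"] = gid
            truths.append(truth)
            meta.append({"genome_id": gid, "clade": clade, "lifestyle": lifestyle})
    return genomes, pd.DataFrame(meta), pd.concat(truths, ignore_index=True)


def simulate_bm_traits(tree: "dendropy.Tree | str", rho: float, seed: int,
                       sigma: float = 1.0) -> tuple[dict[str, float], dict[str, float]]:
    """Two traits evolved along the tree under correlated Brownian motion.

    Each branch adds a bivariate normal increment with per-unit-length
    covariance sigma^2 * [[1, rho], [rho, 1]]; returns {tip: value} maps.
    Independent contrasts on such traits estimate rho.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must be in [-1, 1]")
    t = tree.clone(depth=1) if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    cov = sigma**2 * np.array([[1.0, rho], [rho, 1.0]])
    values = {}
    x_out, y_out = {}, {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        state = np.zeros(2) if parent is None else values[parent]
        blen = node.edge.length or 0.0
        values[node] = state + rng.multivariate_normal([0.0, 0.0], cov * blen) if blen > 0 else state
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            x_out[name], y_out[name] = float(values[node][0]), float(values[node][1])
    return x_out, y_out
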