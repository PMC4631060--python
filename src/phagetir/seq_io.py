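"""Genome I/O and extraction of translation-initiation analysis windows.

Reads annotated genomes (GenBank flat files, or FASTA plus a simple
gene-coordinate table), extracts each qualifying protein-coding sequence
together with the three windows used downstream:

* ``upstream30`` / ``upstream40`` — the 30 / 40 nt immediately 5' of the
  start codon (SD search space and folding window, respectively);
* ``flank_m4p37`` — the 41-nt window from position -4 through +37, where
  +1 is the first base of the start codon and there is no position 0.

Coordinates are 1-based inclusive (GenBank convention). All sequence
analysis downstream is done on the RNA alphabet; this module converts on
extraction, so windows and CDSs are returned with U, never T.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_IUPAC = set("ACGTUNRYSWKMBDHV")

STANDARD_WINDOWS = {"upstream30": (-30, -1), "upstream40": (-40, -1), "flank_m4p37": (-4, 37)}


class EmptyWindowError(ValueError):
    """Requested window lies entirely outside a linear genome."""


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))


def is_unambiguous(seq: str) -> bool:
    return all(c in "ACGU" for c in to_rna(seq))


@dataclass
class GeneCoords:
    """Annotation entry for one CDS: coordinates on the genome.

    ``start``/``end`` are 1-based inclusive; for reverse-strand genes the
    start codon begins at ``end`` and runs toward ``start``.  For compound
    (join) locations ``cds_override`` holds the spliced coding sequence
    while the coordinates keep the 5'-most exon's boundary, which anchors
    all initiation-context windows.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    cds_override: str | None = None


@dataclass
class GenomeAnnotation:
    genome_id: str
    sequence: str  # DNA or RNA, stored uppercase
    topology: str = "linear"  # or "circular"
    genes: list[GeneCoords] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for g in self.genes:
            if not (1 <= g.start <= len(self.sequence) and 1 <= g.end <= len(self.sequence)):
                raise ValueError(f"gene {g.gene_id}: coordinates outside genome")


@dataclass
class GeneRecord:
    """One CDS with its initiation-context windows (sense strand, RNA)."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    cds_seq: str
    upstream30: str
    upstream40: str
    flank_m4p37: str
    truncated: bool = False  # any window shorter than nominal (linear contig edge)
    ambiguous: bool = False  # non-ACGU base in CDS or any window

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3


def read_genome(path: str | Path, table: str | Path | None = None) -> GenomeAnnotation:
    """Read an annotated genome from GenBank, or FASTA plus a coordinate TSV.

    The TSV needs columns gene_id, start, end, strand. GenBank CDS
    features with compound (join) locations are resolved to their 5'-most
    exon for window anchoring, with the spliced sequence kept for codon
    analysis; a warning is logged for each.
    """
    path = Path(path)
    if table is None:
        return _read_genbank(path)
    return _read_fasta_table(path, Path(table))


def _read_genbank(path: Path) -> GenomeAnnotation:
    record = SeqIO.read(str(path), "genbank")
    topology = record.annotations.get("topology", "linear")
    genes: list[GeneCoords] = []
    for i, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        gene_id = (quals.get("locus_tag") or quals.get("gene") or quals.get("protein_id") or [f"CDS_{i}"])[0]
        strand = "-" if feat.location.strand == -1 else "+"
        override = None
        if len(feat.location.parts) > 1:
            logger.warning("%s: compound location for %s; using 5'-most exon boundary for windows", path.name, gene_id)
            override = str(feat.extract(record.seq)).upper()
            parts = feat.location.parts
            if strand == "+":
                start = min(int(p.start) for p in parts) + 1
                end = max(int(p.end) for p in parts)
            else:
                start = min(int(p.start) for p in parts) + 1
                end = max(int(p.end) for p in parts)
        else:
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
        genes.append(GeneCoords(gene_id, start, end, strand, cds_override=override))
    return GenomeAnnotation(record.id or path.stem, str(record.seq), topology, genes)


def _read_fasta_table(fasta: Path, table: Path) -> GenomeAnnotation:
    record = SeqIO.read(str(fasta), "fasta")
    genes = []
    with open(table) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genes.append(GeneCoords(row["gene_id"], int(row["start"]), int(row["end"]), row["strand"]))
    topology = "circular" if "circular" in record.description.lower() else "linear"
    return GenomeAnnotation(record.id or fasta.stem, str(record.seq), topology, genes)


def _offset_to_genomic(gene: GeneCoords, offset: int) -> int:
    """Map a signed start-codon offset (-1 adjacent 5', +1 first AUG base, no 0)."""
    if offset == 0:
        raise ValueError("offset 0 does not exist (-1 is adjacent 5', +1 is first start-codon base)")
    if gene.strand == "+":
        return gene.start + offset + (0 if offset < 0 else -1)
    return gene.end - offset - (0 if offset < 0 else -1)


def extract_window(gene: GeneCoords, genome: GenomeAnnotation, from_pos: int, to_pos: int) -> str:
    """Sense-strand RNA window at signed offsets around the start codon.

    Reverse-strand genes return the reverse complement of the genomic
    segment; circular genomes wrap across the origin; on a linear genome
    the window is truncated at the contig edge (empty result raises
    :class:`EmptyWindowError`).
    """
    if from_pos > to_pos:
        raise ValueError("from_pos must not exceed to_pos")
    n = len(genome.sequence)
    bases: list[str] = []
    for off in range(from_pos, to_pos + 1):
        if off == 0:
            continue
        pos = _offset_to_genomic(gene, off)
        if genome.topology == "circular":
            pos = (pos - 1) % n + 1
        elif not 1 <= pos <= n:
            continue  # truncated at contig edge
        base = to_rna(genome.sequence[pos - 1])
        bases.append(base if gene.strand == "+" else _RNA_COMPLEMENT.get(base, "N"))
    if not bases:
        raise EmptyWindowError(f"window ({from_pos},{to_pos}) of gene {gene.gene_id} lies outside the genome")
    return "".join(bases)


def _expected_len(from_pos: int, to_pos: int) -> int:
    return to_pos - from_pos + 1 - (1 if from_pos < 0 < to_pos else 0)


def build_gene_records(genome: GenomeAnnotation, windows: dict[str, tuple[int, int]] | None = None) -> list[GeneRecord]:
    """Extract every annotated CDS with its analysis windows (unfiltered)."""
    windows = windows or STANDARD_WINDOWS
    records = []
    for gene in genome.genes:
        if gene.cds_override is not None:
            cds = to_rna(gene.cds_override)
        else:
            cds_len = gene.end - gene.start + 1
            cds = extract_window(gene, genome, 1, cds_len)
        extracted, truncated = {}, False
        for name, (lo, hi) in windows.items():
            try:
                w = extract_window(gene, genome, lo, hi)
            except EmptyWindowError:
                w = ""
            if len(w) != _expected_len(lo, hi):
                truncated = True
            extracted[name] = w
        ambiguous = not all(is_unambiguous(s) for s in [cds, *extracted.values()] if s)
        records.append(
            GeneRecord(
                gene_id=gene.gene_id,
                genome_id=genome.genome_id,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_seq=cds,
                truncated=truncated,
                ambiguous=ambiguous,
                **extracted,
            )
        )
    return records


def filter_min_codons(genes: list[GeneRecord], min_codons: int = 33) -> list[GeneRecord]:
    """Drop CDSs shorter than ``min_codons`` codons (default 33).

    Short genes are removed to damp stochastic fluctuation in per-gene
    codon-usage statistics.
    """
    kept = [g for g in genes if len(g.cds_seq) >= 3 * min_codons]
    removed = len(genes) - len(kept)
    if removed:
        logger.info("filter_min_codons: removed %d of %d genes (< %d codons)", removed, len(genes), min_codons)
    return kept


# ---------------------------------------------------------------------------
# writers

def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    cols = ["gene_id", "genome_id", "start", "end", "strand", "upstream30", "upstream40", "flank_m4p37"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for g in genes:
            w.writerow([getattr(g, c) for c in cols])


def write_fasta(genome: GenomeAnnotation, path: str | Path) -> None:
    desc = f"{genome.topology} synthetic" if genome.topology == "circular" else "synthetic"
    SeqIO.write([SeqRecord(Seq(to_dna(genome.sequence)), id=genome.genome_id, description=desc)], str(path), "fasta")


def write_coord_table(genome: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "start", "end", "strand"])
        for g in genome.genes:
            w.writerow([g.gene_id, g.start, g.end, g.strand])


def write_genbank(genome: GenomeAnnotation, path: str | Path) -> None:
    record = SeqRecord(Seq(to_dna(genome.sequence)), id=genome.genome_id, name=genome.genome_id[:16],
                       description="synthetic genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    for g in genome.genes:
        loc = FeatureLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1)
        record.features.append(SeqFeature(loc, type="CDS", qualifiers={"locus_tag": [g.gene_id]}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        SeqIO.write([record], str(path), "genbank")
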