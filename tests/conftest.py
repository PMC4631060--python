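import numpy as np
import pytest

from phagetir.sd_detect import E_COLI_TAIL
from phagetir.seq_io import GeneCoords, GeneRecord, GenomeAnnotation


@pytest.fixture
def tail():
    return E_COLI_TAIL


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gene_record(upstream40: str, cds: str, gene_id: str = "g1", genome_id: str = "G") -> GeneRecord:
    """Assemble a GeneRecord directly from an upstream block and a CDS (RNA)."""
    assert len(upstream40) == 40
    flank = upstream40[-4:] + cds[:37]
    return GeneRecord(gene_id=gene_id, genome_id=genome_id, start=41, end=40 + len(cds),
                      strand="+", cds_seq=cds, upstream30=upstream40[-30:],
                      upstream40=upstream40, flank_m4p37=flank)


def random_seq(rng, n, alphabet="ACGU", p=None):
    return "".join(rng.choice(list(alphabet), size=n, p=p))


@pytest.fixture
def make_genome():
    """Build a GenomeAnnotation around explicit gene placements."""

    def _make(sequence: str, genes: list[tuple], topology: str = "linear", genome_id: str = "G"):
        coords = [GeneCoords(f"g{i+1}", s, e, strand) for i, (s, e, strand) in enumerate(genes)]
        return GenomeAnnotation(genome_id, sequence, topology, coords)

    return _make


def genbank_text(seq: str, cds_locations: list[str], locus: str = "TESTGEN", topology: str = "linear") -> str:
    """Format a minimal GenBank flat file by hand (independent of Biopython's writer)."""
    lines = [
        f"LOCUS       {locus:<17}{len(seq):>11} bp    DNA     {topology:<8} PHG 01-JAN-2000",
        "DEFINITION  synthetic test record.",
        f"ACCESSION   {locus}",
        f"VERSION     {locus}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
    ]
    for i, loc in enumerate(cds_locations):
        lines.append(f"     CDS             {loc}")
        lines.append(f'                     /locus_tag="gene{i+1}"')
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"
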