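"""Shared fixtures: hand-built toy genomes/genes with known structure, and
helpers to fabricate count tables and called sites."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from editome.calling import EditSite
from editome.pileup import BASE_INDEX, SiteCountTable
from editome.reference import (GeneIndex, GeneModel, GenomeReference,
                               reverse_complement)


@dataclass
class BuiltGene:
    model: GeneModel
    seq: str  # genomic-strand sequence of the gene span
    offset: int
    total: int
    strand: str

    def g(self, t: int) -> int:
        """Genomic position of unspliced transcript-sense offset ``t``."""
        if self.strand == "+":
            return self.offset + t
        return self.offset + self.total - 1 - t


def build_gene(gene_id: str, contig: str, strand: str, offset: int,
               pieces: list[tuple[str, str]]) -> BuiltGene:
    """Assemble a gene from transcript-sense pieces.

    ``pieces`` is an ordered list of (kind, sequence) with kind in
    {utr5, cds, intron, utr3}; consecutive non-intron pieces form exons.
    Returns the genomic-strand sequence and a GeneModel with intervals
    mapped for the requested strand.
    """
    total = sum(len(s) for s in (seq for _, seq in pieces))
    gene_seq_ts = "".join(seq for _, seq in pieces)  # transcript sense

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        if strand == "+":
            return (offset + a, offset + b)
        return (offset + total - b, offset + total - a)

    exons, cds, utr5, utr3 = [], [], [], []
    cursor = 0
    exon_start = None
    for kind, seq in pieces:
        a, b = cursor, cursor + len(seq)
        if kind == "intron":
            if exon_start is not None:
                exons.append(to_genomic(exon_start, a))
                exon_start = None
        else:
            if exon_start is None:
                exon_start = a
            if kind == "cds":
                cds.append(to_genomic(a, b))
            elif kind == "utr5":
                utr5.append(to_genomic(a, b))
            elif kind == "utr3":
                utr3.append(to_genomic(a, b))
        cursor = b
    if exon_start is not None:
        exons.append(to_genomic(exon_start, cursor))
    model = GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                      start=offset, end=offset + total,
                      exons=sorted(exons), cds=sorted(cds),
                      utr5=sorted(utr5), utr3=sorted(utr3))
    genomic_seq = gene_seq_ts if strand == "+" else \
        reverse_complement(gene_seq_ts)
    return BuiltGene(model, genomic_seq, offset, total, strand)


# transcript design shared by the plus- and minus-strand toy genes:
# UTR5(4) | CDS exon1: ATG AAA TGG (9) | intron(20) | CDS exon2: CGA TAA (6)
# | UTR3(4) -> protein M K W R *
TOY_PIECES = [
    ("utr5", "GCAG"),
    ("cds", "ATGAAATGG"),
    ("intron", "GTACGTCAGTCAGTCTGTAG"),
    ("cds", "CGATAA"),
    ("utr3", "TCGA"),
]

# a gene whose annotated start codon is GTG (start-gain substrate)
GTG_PIECES = [
    ("utr5", "CTCT"),
    ("cds", "GTGCCATTCTAA"),  # GTG CCA TTC TAA -> V P F *
    ("utr3", "AGGA"),
]


@dataclass
class Toy:
    genome: GenomeReference
    genes: dict[str, BuiltGene]
    index: GeneIndex

    def model(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id].model


@pytest.fixture(scope="session")
def toy() -> Toy:
    """Contig 't1': spacer + plus gene + spacer + minus gene + spacer +
    GTG-start plus gene + spacer."""
    spacer1, spacer2, spacer3, spacer4 = "TTCA", "ACTGCTGA", "CAGTT", "GATC"
    offset_p = len(spacer1)
    gp = build_gene("geneP", "t1", "+", offset_p, TOY_PIECES)
    offset_m = offset_p + gp.total + len(spacer2)
    gm = build_gene("geneM", "t1", "-", offset_m, TOY_PIECES)
    offset_g = offset_m + gm.total + len(spacer3)
    gg = build_gene("geneG", "t1", "+", offset_g, GTG_PIECES)
    seq = spacer1 + gp.seq + spacer2 + gm.seq + spacer3 + gg.seq + spacer4
    genome = GenomeReference({"t1": seq})
    genes = {"geneP": gp, "geneM": gm, "geneG": gg}
    index = GeneIndex([b.model for b in genes.values()])
    return Toy(genome, genes, index)


def make_site(contig="c1", position=10, ref="C", alts=("T",),
              alt_counts=(40,), n=69, k=None, pvalue=1e-9, qvalue=1e-8,
              significant=True, strand_support=None, has_strand=True):
    """Fabricate an EditSite for filter/unit tests."""
    if k is None:
        k = sum(alt_counts)
    if strand_support is None:
        half = k // 2
        strand_support = (half, k - half)
    return EditSite(contig=contig, position=position, ref=ref,
                    alts=tuple(alts), alt_counts=tuple(alt_counts), n=n,
                    k=k, pvalue=pvalue, qvalue=qvalue,
                    significant=significant, strand_support=strand_support,
                    has_strand=has_strand)


def make_count_table(rows, sample_id=None, has_strand=True):
    """rows: list of (contig, pos0, ref, {base: (fwd, rev) | int}).
    Integer counts are placed on the forward strand."""
    contigs, poss, refs, counts = [], [], [], []
    for contig, pos, ref, base_counts in rows:
        arr = np.zeros((4, 2), dtype=np.int64)
        for base, val in base_counts.items():
            if isinstance(val, tuple):
                arr[BASE_INDEX[base]] = val
            else:
                arr[BASE_INDEX[base], 0] = val
        contigs.append(contig)
        poss.append(pos)
        refs.append(ref)
        counts.append(arr)
    if not rows:
        return SiteCountTable.empty(sample_id)
    return SiteCountTable(contigs, poss, refs, np.stack(counts),
                          sample_id=sample_id, has_strand=has_strand)
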