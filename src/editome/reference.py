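"""Genome and gene-model handling with strand-aware coordinate services.

Internal coordinates are 0-based half-open throughout; conversion to/from
1-based inclusive happens only at file boundaries (FASTA indexing is
implicit, GFF3 is 1-based inclusive).
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeReference:
    """Container for contig sequences (uppercase A/C/G/T/N).

    Out-of-range lookups raise ``KeyError`` (unknown contig) or
    ``IndexError`` (position outside the contig).
    """

    def __init__(self, contigs: dict[str, str]):
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid bases: {sorted(bad)}"
                )
            clean[name] = seq
        self.contigs = clean

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __iter__(self):
        return iter(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def base(self, contig: str, pos: int) -> str:
        """Reference base at 0-based ``pos``."""
        seq = self.contigs[contig]
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} outside contig {contig!r} "
                             f"(length {len(seq)})")
        return seq[pos]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open interval [start, end)."""
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"interval [{start},{end}) outside contig {contig!r}")
        return seq[start:end]


def load_genome(fasta_path) -> GenomeReference:
    """Load a multi-contig FASTA; lowercase is normalised to uppercase."""
    contigs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            contigs[rec.id] = str(rec.seq)
    except ValueError as exc:  # Biopython parse errors
        raise ValueError(f"malformed FASTA {fasta_path}: {exc}") from exc
    if not contigs:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return GenomeReference(contigs)


@dataclass
class GeneModel:
    """A stranded gene with exon/intron/CDS/UTR structure.

    All intervals are 0-based half-open genomic coordinates stored in
    genomic-ascending order; transcript-sense ordering is derived on demand
    for minus-strand genes.
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    cds_valid: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = -1
        for s, e in self.exons:
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        if self.cds:
            if self.cds_length % 3 != 0:
                warnings.warn(
                    f"gene {self.gene_id}: CDS length {self.cds_length} not "
                    "divisible by 3; excluded from effect annotation")
                self.cds_valid = False
            if not self.utr5 and not self.utr3:
                self._derive_utrs()

    # -- basic geometry -------------------------------------------------
    @property
    def span_length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic-ascending."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def is_intronic(self, pos: int) -> bool:
        return self.contains(pos) and not self.is_exonic(pos)

    def is_cds(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds)

    # -- transcript-sense services --------------------------------------
    def transcript_exons(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def gene_offset(self, pos: int) -> int:
        """Transcript-sense offset of ``pos`` within the gene span."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside gene {self.gene_id}")
        if self.strand == "+":
            return pos - self.start
        return (self.end - 1) - pos

    def cds_offset(self, pos: int) -> int | None:
        """Transcript-sense offset of ``pos`` within the spliced CDS,
        or None if the position is not in the CDS."""
        if not self.is_cds(pos):
            return None
        off = 0
        intervals = self.cds if self.strand == "+" else self.cds[::-1]
        for s, e in intervals:
            if s <= pos < e:
                off += (pos - s) if self.strand == "+" else (e - 1 - pos)
                return off
            off += e - s
        return None  # pragma: no cover

    def spliced_cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcript order."""
        out: list[int] = []
        for s, e in (self.cds if self.strand == "+" else self.cds[::-1]):
            rng = range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)
            out.extend(rng)
        return out

    def spliced_cds_sequence(self, genome: GenomeReference) -> str:
        parts = [genome.slice(self.contig, s, e) for s, e in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def _derive_utrs(self):
        """Fill UTR intervals from exonic regions outside the CDS,
        sided in transcript sense (SnpEff-like behaviour for gene models
        without explicit UTR records)."""
        cds_start = self.cds[0][0]
        cds_end = self.cds[-1][1]
        before, after = [], []  # genomic-left / genomic-right of CDS
        for s, e in self.exons:
            if s < cds_start:
                before.append((s, min(e, cds_start)))
            if e > cds_end:
                after.append((max(s, cds_end), e))
        if self.strand == "+":
            self.utr5, self.utr3 = before, after
        else:
            self.utr5, self.utr3 = after, before


@dataclass(frozen=True)
class OrientedEdit:
    """An edit expressed both in genomic and transcript-sense bases."""

    contig: str
    position: int  # 0-based
    genomic_ref: str
    genomic_alt: str
    ref: str  # transcript-sense
    alt: str  # transcript-sense
    gene_id: str  # or "intergenic"
    ambiguous_strand: bool = False

    @property
    def edit_type(self) -> str:
        return f"{self.ref}-to-{self.alt}"


class GeneIndex:
    """Interval lookup of genes by contig + position (genes may overlap)."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        self._by_contig: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_contig.setdefault(g.contig, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._maxlen: dict[str, int] = {}
        for contig, gl in self._by_contig.items():
            gl.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._starts[contig] = [g.start for g in gl]
            self._maxlen[contig] = max(g.span_length for g in gl)

    def overlapping(self, contig: str, pos: int) -> list[GeneModel]:
        gl = self._by_contig.get(contig)
        if not gl:
            return []
        starts = self._starts[contig]
        lo = bisect.bisect_right(starts, pos - self._maxlen[contig])
        hi = bisect.bisect_right(starts, pos)
        return [g for g in gl[lo:hi] if g.contains(pos)]

    def assign(self, contig: str, pos: int) -> GeneModel | None:
        """Assign a position to the most specific (smallest-span) gene;
        ties broken by gene id for determinism."""
        hits = self.overlapping(contig, pos)
        if not hits:
            return None
        return min(hits, key=lambda g: (g.span_length, g.gene_id))


def load_gene_models(gff_path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/exon/CDS, optional UTR features).

    Genes lacking CDS are carried with an empty CDS list; genes whose CDS
    length is not divisible by 3 are kept but flagged ``cds_valid=False``.
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(g):
            iv = (child.start - 1, child.end)  # to 0-based half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype in ("five_prime_UTR", "5UTR"):
                utr5.append(iv)
            elif child.featuretype in ("three_prime_UTR", "3UTR"):
                utr3.append(iv)
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(GeneModel(
            gene_id=g.id, contig=g.seqid, strand=g.strand,
            start=g.start - 1, end=g.end,
            exons=exons, cds=cds, utr5=sorted(utr5), utr3=sorted(utr3)))
    return genes


def orient_edit(contig: str, position: int, ref: str, alt: str,
                gene_index: GeneIndex,
                genome: GenomeReference | None = None) -> OrientedEdit:
    """Express an edit in transcript sense.

    Edits inside minus-strand (Crick) genes are complemented; edits in
    plus-strand genes or intergenic regions keep their genomic bases.
    Positions covered by genes on both strands are resolved by the
    smallest-span gene and flagged ambiguous.
    """
    if genome is not None and genome.base(contig, position) != ref:
        raise ValueError(
            f"{contig}:{position}: ref base {ref!r} disagrees with genome "
            f"base {genome.base(contig, position)!r}")
    hits = gene_index.overlapping(contig, position)
    ambiguous = len({g.strand for g in hits}) > 1
    gene = gene_index.assign(contig, position)
    if gene is None:
        return OrientedEdit(contig, position, ref, alt, ref, alt, "intergenic")
    if gene.strand == "+":
        return OrientedEdit(contig, position, ref, alt, ref, alt,
                            gene.gene_id, ambiguous)
    return OrientedEdit(contig, position, ref, alt,
                        complement(ref), complement(alt),
                        gene.gene_id, ambiguous)
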