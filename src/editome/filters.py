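"""Post-calling filter cascade.

Five pure, order-independent predicates applied to significance-called
sites: edit-frequency bounds, window uniqueness against the genome, strand
bias of edit-supporting reads, intron-edge proximity, and DNA-seq
concordance. Every site records a flag per filter; survivors pass all, and
an audit table reports counts remaining after each stage in fixed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from editome.calling import EditSite
from editome.reference import GeneIndex, GenomeReference, reverse_complement

PASS = "pass"
FAIL = "fail"
NOT_EVALUABLE = "not_evaluable"
FLAGGED = "flagged"  # passing, but with a caveat (e.g. no DNA coverage)

FILTER_ORDER = ("frequency", "uniqueness", "strand_bias", "intron_edge",
                "dna_concordance")


@dataclass(frozen=True)
class FilterConfig:
    min_frequency: float = 0.05
    max_frequency: float = 0.95
    uniqueness_flank: int = 100  # bases each side -> 201-bp window
    uniqueness_evalue: float = 1e-5
    strand_bias_threshold: float = 0.85  # strict >
    intron_edge_margin: int = 9
    dna_mode: str = "strict"  # "strict" | "flagged"

    def __post_init__(self):
        if not 0 <= self.min_frequency < self.max_frequency <= 1:
            raise ValueError("need 0 <= min_frequency < max_frequency <= 1")
        if self.uniqueness_flank < 1:
            raise ValueError("uniqueness_flank must be >= 1")
        if self.intron_edge_margin < 0:
            raise ValueError("intron_edge_margin must be >= 0")
        if self.dna_mode not in ("strict", "flagged"):
            raise ValueError("dna_mode must be 'strict' or 'flagged'")


# ---------------------------------------------------------------------------
# individual predicates


def frequency_filter(site: EditSite, config: FilterConfig) -> str:
    """Pass iff min <= f <= max, bounds inclusive."""
    f = site.frequency
    return PASS if config.min_frequency <= f <= config.max_frequency else FAIL


def strand_bias_filter(site: EditSite, config: FilterConfig) -> str:
    """Fail iff the edit-supporting reads are overrepresented on one strand
    (strictly above the threshold). Not evaluable without strand counts."""
    if not site.has_strand:
        return NOT_EVALUABLE
    fwd, rev = site.strand_support
    total = fwd + rev
    if total == 0:
        return NOT_EVALUABLE
    return FAIL if max(fwd, rev) / total > config.strand_bias_threshold \
        else PASS


def intron_edge_filter(site: EditSite, gene_index: GeneIndex,
                       config: FilterConfig) -> str:
    """Fail iff the site lies within ``margin`` bases of either end of any
    annotated intron (ends inclusive)."""
    m = config.intron_edge_margin
    for gene in gene_index.overlapping(site.contig, site.position):
        for s, e in gene.introns:
            if s <= site.position < min(s + m, e) \
                    or max(e - m, s) <= site.position < e:
                return FAIL
    return PASS


def dna_concordance_filter(site: EditSite, dna_counts,
                           config: FilterConfig) -> str:
    """Strict mode: pass iff DNA coverage >= 1 and 100% of DNA reads carry
    the reference base. Flagged mode: zero-coverage sites pass with a flag."""
    row = dna_counts.row(site.contig, site.position)
    if row is None:
        cov = 0
    else:
        cov = int(dna_counts.n[row])
    if cov == 0:
        return FAIL if config.dna_mode == "strict" else FLAGGED
    from editome.pileup import BASE_INDEX
    ref_reads = int(dna_counts.base_counts[row, BASE_INDEX[site.ref]])
    return PASS if ref_reads == cov else FAIL


# ---------------------------------------------------------------------------
# uniqueness: BLAST-table mode and internal seed-and-extend mode

class BlastHitsTable:
    """Qualifying hits from a BLAST tabular (outfmt 6) file.

    Query ids must follow the window convention ``contig:start-end``
    (1-based inclusive window coordinates). A hit qualifies when its
    e-value is at or below the cutoff and it is not the window's self-hit.
    """

    def __init__(self, path):
        cols = ["qseqid", "sseqid", "pident", "length", "mismatch",
                "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                "bitscore"]
        self.df = pd.read_csv(path, sep="\t", names=cols, comment="#")

    def has_other_locus_hit(self, contig: str, wstart: int, wend: int,
                            evalue_cutoff: float) -> bool:
        """``wstart``/``wend``: 0-based half-open window on ``contig``."""
        qid = f"{contig}:{wstart + 1}-{wend}"
        hits = self.df[(self.df.qseqid == qid)
                       & (self.df.evalue <= evalue_cutoff)]
        for _, h in hits.iterrows():
            s_lo = min(h.sstart, h.send) - 1
            s_hi = max(h.sstart, h.send)
            if h.sseqid == contig and s_lo < wend and s_hi > wstart:
                continue  # self-hit (overlaps the window's own locus)
            return True
        return False


# ungapped Karlin-Altschul parameters for match +2 / mismatch -3
_KA_LAMBDA = 0.625
_KA_K = 0.41
_MATCH, _MISMATCH = 2, -3
_XDROP = 30


class GenomeSelfAligner:
    """Seed-and-extend locator of near-duplicate windows in the genome,
    used when no external BLAST hit table is supplied.

    Exact seeds of ``seed_len`` bases are looked up in a genome-wide k-mer
    index (both orientations), extended ungapped with an X-drop, and scored
    with a Karlin-Altschul e-value under default nucleotide scoring
    (match +2, mismatch -3)."""

    def __init__(self, genome: GenomeReference, seed_len: int = 16):
        self.genome = genome
        self.seed_len = seed_len
        self.search_space = genome.total_length
        self.index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in genome.contigs.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i:i + seed_len]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((contig, i))

    @staticmethod
    def _extend(query: str, qi: int, subject: str, si: int,
                seed_len: int) -> int:
        """Ungapped X-drop extension around a seeded match; returns the
        best local score."""
        score = best = seed_len * _MATCH
        q, s = qi + seed_len, si + seed_len
        while q < len(query) and s < len(subject):
            score += _MATCH if query[q] == subject[s] else _MISMATCH
            best = max(best, score)
            if best - score > _XDROP:
                break
            q += 1
            s += 1
        score = best
        q, s = qi - 1, si - 1
        while q >= 0 and s >= 0:
            score += _MATCH if query[q] == subject[s] else _MISMATCH
            best = max(best, score)
            if best - score > _XDROP:
                break
            q -= 1
            s -= 1
        return best

    def _evalue(self, score: int, window_len: int) -> float:
        return _KA_K * window_len * self.search_space \
            * math.exp(-_KA_LAMBDA * score)

    def has_other_locus_hit(self, contig: str, wstart: int, wend: int,
                            evalue_cutoff: float) -> bool:
        window = self.genome.slice(contig, wstart, wend)
        L = len(window)
        k = self.seed_len
        for query, is_rc in ((window, False), (reverse_complement(window),
                                               True)):
            seen: set = set()
            for qi in range(0, L - k + 1):
                seed = query[qi:qi + k]
                for hc, hi in self.index.get(seed, ()):
                    # skip the window's own locus (forward self-match)
                    if not is_rc and hc == contig \
                            and wstart - L < hi < wend:
                        continue
                    diag = (hc, hi - qi, is_rc)
                    if diag in seen:
                        continue
                    seen.add(diag)
                    score = self._extend(query, qi, self.genome.contigs[hc],
                                         hi, k)
                    if self._evalue(score, L) <= evalue_cutoff:
                        return True
        return False


def uniqueness_filter(site: EditSite, genome: GenomeReference,
                      config: FilterConfig, hits=None) -> str:
    """Fail iff the flank window around the site has a qualifying match to
    another locus. ``hits`` is a :class:`BlastHitsTable` or
    :class:`GenomeSelfAligner`; windows are clipped at contig edges."""
    if hits is None:
        raise ValueError("uniqueness_filter needs a hits table (external "
                         "BLAST outfmt 6) or a GenomeSelfAligner (internal "
                         "mode)")
    ws = max(0, site.position - config.uniqueness_flank)
    we = min(genome.length(site.contig),
             site.position + config.uniqueness_flank + 1)
    return FAIL if hits.has_other_locus_hit(
        site.contig, ws, we, config.uniqueness_evalue) else PASS


# ---------------------------------------------------------------------------
# cascade


def apply_filters(sites: list[EditSite], genome: GenomeReference,
                  gene_index: GeneIndex, dna_counts=None, hits=None,
                  config: FilterConfig | None = None):
    """Apply all filters, record flags, and build the audit table.

    Returns (survivors, audit) where audit is a DataFrame of counts
    remaining after each stage in the fixed order frequency -> uniqueness
    -> strand bias -> intron edge -> DNA concordance. Filters whose inputs
    are unavailable (no hits source, no DNA table) mark sites not-evaluable
    and remove nothing. Flags are only assigned once per filter.
    """
    config = config or FilterConfig()
    aligner = hits
    if aligner is None and genome.total_length <= 10_000_000:
        aligner = GenomeSelfAligner(genome)
    for site in sites:
        site.flags["frequency"] = frequency_filter(site, config)
        if aligner is not None:
            site.flags["uniqueness"] = uniqueness_filter(
                site, genome, config, aligner)
        else:
            site.flags["uniqueness"] = NOT_EVALUABLE
        site.flags["strand_bias"] = strand_bias_filter(site, config)
        site.flags["intron_edge"] = intron_edge_filter(
            site, gene_index, config)
        if dna_counts is not None:
            site.flags["dna_concordance"] = dna_concordance_filter(
                site, dna_counts, config)
        else:
            site.flags["dna_concordance"] = NOT_EVALUABLE
    remaining = list(sites)
    audit_rows = [{"stage": "input", "remaining": len(remaining)}]
    for name in FILTER_ORDER:
        remaining = [s for s in remaining if s.flags[name] != FAIL]
        audit_rows.append({"stage": name, "remaining": len(remaining)})
    audit = pd.DataFrame(audit_rows)
    return remaining, audit
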