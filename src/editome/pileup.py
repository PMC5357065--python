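"""Per-site, per-strand base counts from alignments or precomputed tables.

The counting contract mirrors the upstream tool settings the calling model
expects: the first and last ``end_trim`` bases of every read are ignored
(default 9), non-uniquely mapped reads contribute nothing, reads are
de-duplicated per sample, and positions inside homopolymer runs are masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from editome.reference import GenomeReference

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STRANDS = "+-"
_COUNT_COLUMNS = [f"{b}{s}" for b in BASES for s in STRANDS]


@dataclass(frozen=True)
class HomopolymerMask:
    """Positions inside maximal runs of >= ``min_run`` identical bases."""

    positions: frozenset
    min_run: int

    def __contains__(self, key) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def mask_homopolymers(genome: GenomeReference, min_run: int = 4) -> HomopolymerMask:
    """Mask every position inside a run of >= ``min_run`` identical
    reference bases. 'N' never forms a run."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    masked = set()
    for contig, seq in genome.contigs.items():
        i, L = 0, len(seq)
        while i < L:
            j = i + 1
            while j < L and seq[j] == seq[i]:
                j += 1
            if seq[i] != "N" and j - i >= min_run:
                masked.update((contig, p) for p in range(i, j))
            i = j
    return HomopolymerMask(frozenset(masked), min_run)


class SiteCountTable:
    """Per-position, per-base, per-strand read counts for one sample
    (or a pool of samples).

    Rows are sorted by (contig, position); ``counts`` has shape
    (n_sites, 4 bases, 2 strands). Positions are 0-based internally.
    """

    def __init__(self, contig, pos, ref, counts, sample_id=None,
                 has_strand=True):
        order = np.lexsort((pos, contig))
        self.contig = np.asarray(contig, dtype=object)[order]
        self.pos = np.asarray(pos, dtype=np.int64)[order]
        self.ref = np.asarray(ref, dtype="<U1")[order]
        self.counts = np.asarray(counts, dtype=np.int64)[order]
        if self.counts.shape != (len(self.pos), 4, 2):
            raise ValueError("counts must have shape (n, 4, 2)")
        self.sample_id = sample_id
        self.has_strand = has_strand
        self._index: dict | None = None

    # -- construction ---------------------------------------------------
    @classmethod
    def empty(cls, sample_id=None):
        return cls(np.empty(0, object), np.empty(0, np.int64),
                   np.empty(0, "<U1"), np.empty((0, 4, 2), np.int64),
                   sample_id=sample_id)

    @classmethod
    def from_dict(cls, counts: dict, refs: dict, sample_id=None,
                  has_strand=True):
        """Build from {(contig, pos): (4,2) array} plus {(contig,pos): ref}."""
        keys = list(counts)
        if not keys:
            return cls.empty(sample_id)
        contig = [k[0] for k in keys]
        pos = [k[1] for k in keys]
        ref = [refs[k] for k in keys]
        arr = np.stack([np.asarray(counts[k]) for k in keys])
        return cls(contig, pos, ref, arr, sample_id, has_strand)

    # -- accessors ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n(self) -> np.ndarray:
        """Total coverage per site."""
        return self.counts.sum(axis=(1, 2))

    @property
    def base_counts(self) -> np.ndarray:
        """(n_sites, 4) counts summed over strands."""
        return self.counts.sum(axis=2)

    def _build_index(self):
        if self._index is None:
            self._index = {(c, p): i for i, (c, p)
                           in enumerate(zip(self.contig, self.pos))}
        return self._index

    def row(self, contig: str, pos: int) -> int | None:
        return self._build_index().get((contig, pos))

    def site_counts(self, contig: str, pos: int) -> np.ndarray | None:
        i = self.row(contig, pos)
        return None if i is None else self.counts[i]

    # -- operations -----------------------------------------------------
    @classmethod
    def merge(cls, tables, sample_id="pooled"):
        """Position-wise sum of several tables (the pooled calling input)."""
        tables = [t for t in tables if len(t)]
        if not tables:
            return cls.empty(sample_id)
        frames = []
        for t in tables:
            df = pd.DataFrame(t.counts.reshape(len(t), 8),
                              columns=_COUNT_COLUMNS)
            df.insert(0, "ref", t.ref)
            df.insert(0, "pos", t.pos)
            df.insert(0, "contig", t.contig)
            frames.append(df)
        cat = pd.concat(frames, ignore_index=True)
        refcheck = cat.groupby(["contig", "pos"])["ref"].nunique()
        if (refcheck > 1).any():
            raise ValueError("inconsistent reference bases across tables")
        agg = (cat.groupby(["contig", "pos"], as_index=False)
                  .agg({"ref": "first", **{c: "sum" for c in _COUNT_COLUMNS}}))
        counts = agg[_COUNT_COLUMNS].to_numpy().reshape(len(agg), 4, 2)
        return cls(agg["contig"].to_numpy(object), agg["pos"].to_numpy(),
                   agg["ref"].to_numpy(), counts, sample_id,
                   has_strand=all(t.has_strand for t in tables))

    # -- I/O ------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "contig": self.contig,
            "position": self.pos + 1,  # 1-based on disk
            "ref": self.ref,
        })
        flat = self.counts.reshape(len(self), 8)
        for j, col in enumerate(_COUNT_COLUMNS):
            df[col] = flat[:, j]
        return df

    def to_tsv(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def read_count_table(tsv_path, genome: GenomeReference | None = None,
                     sample_id=None) -> SiteCountTable:
    """Read a per-site count table.

    Expected columns: ``contig``, ``position`` (1-based), ``ref`` and
    either per-strand counts (``A+ A- C+ C- G+ G- T+ T-``) or plain
    per-base counts (``A C G T``; strand information then unavailable and
    the strand-bias filter reports not-evaluable).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"contig": str})
    if df.empty:
        return SiteCountTable.empty(sample_id)
    required = {"contig", "position", "ref"}
    if not required <= set(df.columns):
        raise ValueError(f"count table missing columns {required - set(df.columns)}")
    has_strand = all(c in df.columns for c in _COUNT_COLUMNS)
    n = len(df)
    counts = np.zeros((n, 4, 2), dtype=np.int64)
    if has_strand:
        counts = df[_COUNT_COLUMNS].to_numpy().reshape(n, 4, 2)
    elif all(b in df.columns for b in BASES):
        counts[:, :, 0] = df[list(BASES)].to_numpy()
    else:
        raise ValueError("count table has neither per-strand nor per-base "
                         "count columns")
    pos = df["position"].to_numpy() - 1
    ref = df["ref"].astype(str).str.upper().to_numpy()
    contig = df["contig"].to_numpy(object)
    if genome is not None:
        for c, p, r in zip(contig, pos, ref):
            gbase = genome.base(c, int(p))
            if gbase != r:
                raise ValueError(
                    f"{c}:{p + 1}: table ref {r!r} disagrees with genome "
                    f"{gbase!r}")
    return SiteCountTable(contig, pos, ref, counts, sample_id, has_strand)


# -- SAM handling --------------------------------------------------------

def _dedup_key(read: pysam.AlignedSegment):
    if read.is_paired:
        return (read.reference_name, read.reference_start,
                read.next_reference_start, read.is_reverse, read.is_read1)
    return (read.reference_name, read.reference_start, read.is_reverse)


def is_unique(read: pysam.AlignedSegment) -> bool:
    """Default uniqueness predicate: mapping quality > 0 and no
    multi-hit annotation (NH tag > 1)."""
    if read.mapping_quality == 0:
        return False
    if read.has_tag("NH") and read.get_tag("NH") > 1:
        return False
    return True


def deduplicate_alignments(reads):
    """Keep one representative per (contig, start, mate-start, strand) key;
    unpaired reads are keyed on (contig, start, strand)."""
    seen = set()
    out = []
    for read in reads:
        key = _dedup_key(read)
        if key in seen:
            continue
        seen.add(key)
        out.append(read)
    return out


def pileup_from_sam(sam_path, genome: GenomeReference,
                    mask: HomopolymerMask | None = None,
                    end_trim: int = 9, unique_only: bool = True,
                    dedup: bool = True, min_base_quality: int | None = None,
                    sample_id=None) -> SiteCountTable:
    """Base counts from a SAM file under the counting contract.

    Each read contributes base calls only at read offsets
    ``[end_trim, read_length - end_trim)``; insertions and deletions never
    contribute; masked positions are absent from the output.
    """
    counts: dict = {}
    refs: dict = {}
    skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        reads = (r for r in sam
                 if not (r.is_unmapped or r.is_secondary or r.is_supplementary))
        if unique_only:
            reads = (r for r in reads if is_unique(r))
        if dedup:
            reads = deduplicate_alignments(reads)
        for read in reads:
            seq = read.query_sequence
            if seq is None:
                skipped += 1
                continue
            quals = read.query_qualities
            qlen = len(seq)
            lo, hi = end_trim, qlen - end_trim
            contig = read.reference_name
            if contig not in genome:
                skipped += 1
                continue
            strand = 1 if read.is_reverse else 0
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if not lo <= qpos < hi:
                    continue
                base = seq[qpos]
                if base not in BASE_INDEX:
                    continue
                if min_base_quality is not None and quals is not None \
                        and quals[qpos] < min_base_quality:
                    continue
                key = (contig, rpos)
                if mask is not None and key in mask:
                    continue
                if key not in counts:
                    counts[key] = np.zeros((4, 2), dtype=np.int64)
                    refs[key] = genome.base(contig, rpos)
                counts[key][BASE_INDEX[base], strand] += 1
    if skipped:
        logger.warning("pileup_from_sam: skipped %d unusable records", skipped)
    return SiteCountTable.from_dict(counts, refs, sample_id)
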