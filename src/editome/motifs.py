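"""Sequence-context window extraction per edit type and the train/test
split used to feed an external motif discovery tool.

Windows are emitted in transcript sense (minus-strand genes are
reverse-complemented). ``genic`` context uses the unspliced gene sequence;
``exonic`` uses the spliced transcript. Windows truncated at feature
boundaries are emitted at reduced length with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from editome.reference import (GeneIndex, GeneModel, GenomeReference,
                               complement, reverse_complement)


@dataclass
class ContextWindow:
    contig: str
    position: int  # 0-based genomic position of the focal edit
    gene_id: str
    edit_type: str  # transcript-sense, e.g. "C-to-T"
    sequence: str
    truncated: bool
    n_edits: int = 1  # edited positions inside the window (incl. focal)

    @property
    def name(self) -> str:
        return (f"{self.contig}:{self.position + 1}|{self.gene_id}"
                f"|{self.edit_type}|edits={self.n_edits}"
                + ("|truncated" if self.truncated else ""))


def _genic_window(gene: GeneModel, genome: GenomeReference, pos: int,
                  flank: int):
    lo = max(gene.start, pos - flank)
    hi = min(gene.end, pos + flank + 1)
    seq = genome.slice(gene.contig, lo, hi)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    covered = set(range(lo, hi))
    return seq, hi - lo < 2 * flank + 1, covered


def _exonic_window(gene: GeneModel, genome: GenomeReference, pos: int,
                   flank: int):
    spliced_pos: list[int] = []
    for s, e in gene.transcript_exons():
        rng = range(s, e) if gene.strand == "+" else range(e - 1, s - 1, -1)
        spliced_pos.extend(rng)
    if pos not in spliced_pos:
        return None
    idx = spliced_pos.index(pos)
    lo = max(0, idx - flank)
    hi = min(len(spliced_pos), idx + flank + 1)
    window_pos = spliced_pos[lo:hi]
    bases = [genome.base(gene.contig, p) for p in window_pos]
    if gene.strand == "-":
        # transcript order is already right-to-left; complement each base
        bases = [complement(b) for b in bases]
    seq = "".join(bases)
    return seq, hi - lo < 2 * flank + 1, set(window_pos)


def extract_windows(oriented_edits, genome: GenomeReference,
                    gene_index: GeneIndex, flank: int = 100,
                    context: str = "genic"
                    ) -> dict[str, list[ContextWindow]]:
    """Group per-edit sequence contexts by oriented edit type.

    ``oriented_edits`` are :class:`~editome.reference.OrientedEdit`
    instances. Intergenic edits (and, in exonic mode, intronic edits) are
    skipped.
    """
    if context not in ("genic", "exonic"):
        raise ValueError("context must be 'genic' or 'exonic'")
    genes = {g.gene_id: g for g in gene_index.genes}
    edited_positions: dict[str, set[int]] = {}
    for e in oriented_edits:
        if e.gene_id != "intergenic":
            edited_positions.setdefault(e.gene_id, set()).add(e.position)
    out: dict[str, list[ContextWindow]] = {}
    for e in oriented_edits:
        if e.gene_id == "intergenic":
            continue
        gene = genes[e.gene_id]
        if context == "genic":
            seq, truncated, covered = _genic_window(gene, genome,
                                                    e.position, flank)
        else:
            res = _exonic_window(gene, genome, e.position, flank)
            if res is None:
                continue  # intronic edit in exonic mode
            seq, truncated, covered = res
        n_edits = len(edited_positions[e.gene_id] & covered)
        out.setdefault(e.edit_type, []).append(ContextWindow(
            contig=e.contig, position=e.position, gene_id=e.gene_id,
            edit_type=e.edit_type, sequence=seq, truncated=truncated,
            n_edits=n_edits))
    return out


def split_train_test(windows: list[ContextWindow], seed: int = 0):
    """Random half split, then windows containing more than one edit are
    moved from train to test (so train holds single-edit windows only)."""
    if len(windows) < 2:
        return list(windows), []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(windows))
    half = len(windows) // 2
    train = [windows[i] for i in order[:half]]
    test = [windows[i] for i in order[half:]]
    moved = [w for w in train if w.n_edits > 1]
    train = [w for w in train if w.n_edits <= 1]
    test.extend(moved)
    return train, test


def sample_background_windows(gene_index: GeneIndex,
                              genome: GenomeReference,
                              edits_by_gene: dict[str, set[int]],
                              n: int = 10_000, length: int = 201,
                              seed: int = 0) -> list[ContextWindow]:
    """Uniformly sample windows from genes with zero edits (transcript
    sense, unspliced gene sequence), for motif false-negative evaluation."""
    rng = np.random.default_rng(seed)
    eligible = [g for g in gene_index.genes
                if g.span_length >= length
                and not edits_by_gene.get(g.gene_id)]
    if not eligible:
        return []
    out = []
    for _ in range(n):
        gene = eligible[rng.integers(len(eligible))]
        start = int(rng.integers(gene.start, gene.end - length + 1))
        seq = genome.slice(gene.contig, start, start + length)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        out.append(ContextWindow(
            contig=gene.contig, position=start + length // 2,
            gene_id=gene.gene_id, edit_type="background", sequence=seq,
            truncated=False, n_edits=0))
    return out


def write_fasta(windows: list[ContextWindow], path):
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.name}\n{w.sequence}\n")
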