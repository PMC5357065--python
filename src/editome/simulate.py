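"""Synthetic genome / editome / count-table generator.

Produces a haploid reference with planted multi-exon genes on both
strands, a ground-truth editome with per-condition edit frequencies
(optionally condition-shifted for a subset of genes), and per-sample
RNA-seq and DNA-seq count tables with negative-binomial coverage,
uniform-miscall sequencing error and per-read strand allocation. All
randomness flows from a single integer seed, so outputs are
bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from editome.pileup import (BASE_INDEX, BASES, SiteCountTable,
                            mask_homopolymers)
from editome.reference import GeneModel, GenomeReference, reverse_complement

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)
                 if "".join(c) not in _STOP_CODONS]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # genome / genes
    n_genes: int = 20
    intergenic_length: tuple[int, int] = (100, 400)
    exons_per_gene: tuple[int, int] = (1, 4)
    cds_codons: tuple[int, int] = (60, 160)
    intron_length: tuple[int, int] = (60, 200)
    utr_length: tuple[int, int] = (30, 90)
    minus_strand_prob: float = 0.5
    # editome
    n_edit_sites: int = 60
    edits_per_gene: int | None = None  # None -> random allocation
    hosting_gene_fraction: float = 0.6
    edit_frequency_range: tuple[float, float] = (0.1, 0.9)
    control_frequency: float | None = None  # fixed design override
    stress_frequency: float | None = None  # frequency in shifted genes/conds
    shifted_gene_fraction: float = 0.0
    shift_conditions: tuple[str, ...] = ("heat",)
    cluster_edits: bool = False  # place each gene's edits in a tight run
    # sequencing
    conditions: tuple[str, ...] = ("control", "cold", "heat", "dark")
    replicates: int = 4
    coverage_mean: float = 69.0
    coverage_dispersion: float = 10.0  # negative-binomial size parameter
    error_rate: float = 0.01
    dna_error_rate: float = 0.0
    dna_coverage_mean: float = 30.0
    fwd_read_prob: float = 0.5
    # fixtures
    duplication: bool = False  # copy a 201-bp edited window elsewhere
    homopolymer_min_run: int = 4
    intron_edge_margin: int = 9

    def __post_init__(self):
        for p in (self.minus_strand_prob, self.shifted_gene_fraction,
                  self.error_rate, self.dna_error_rate, self.fwd_read_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulationBundle:
    config: SimulationConfig
    genome: GenomeReference
    genes: list[GeneModel]
    truth: pd.DataFrame
    rna_tables: dict[tuple[str, str], SiteCountTable] = field(
        default_factory=dict)
    dna_table: SiteCountTable | None = None

    def pooled_rna(self) -> SiteCountTable:
        return SiteCountTable.merge(list(self.rna_tables.values()))


# ---------------------------------------------------------------------------
# reference generation


def _random_seq(rng, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def _u(rng, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def _build_gene(rng, config: SimulationConfig, gene_id: str, contig: str,
                offset: int) -> tuple[str, GeneModel]:
    """Construct one gene's genomic sequence plus its model.

    The transcript is built 5'->3' (UTR5 + ATG + sense codons + stop +
    UTR3), split into exons with introns in between, then laid onto the
    genome (reverse-complemented for minus-strand genes).
    """
    utr5_len = _u(rng, config.utr_length)
    utr3_len = _u(rng, config.utr_length)
    n_codons = _u(rng, config.cds_codons)
    cds = "ATG" + "".join(
        _SENSE_CODONS[i]
        for i in rng.integers(0, len(_SENSE_CODONS), n_codons)) + "TAA"
    transcript = _random_seq(rng, utr5_len) + cds + _random_seq(rng, utr3_len)
    t_len = len(transcript)
    n_exons = min(_u(rng, config.exons_per_gene), max(1, t_len // 60))
    # exon boundaries in transcript coordinates
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(20, t_len - 20), size=n_exons - 1,
                                  replace=False))
        while np.any(np.diff(cuts) < 20):
            cuts = np.sort(rng.choice(np.arange(20, t_len - 20),
                                      size=n_exons - 1, replace=False))
        bounds = [0, *cuts.tolist(), t_len]
    else:
        bounds = [0, t_len]
    exon_tr = list(zip(bounds[:-1], bounds[1:]))  # transcript coords
    introns = [_random_seq(rng, _u(rng, config.intron_length))
               for _ in range(n_exons - 1)]
    # unspliced gene sequence in transcript sense + exon offsets within it
    pieces, exon_un = [], []
    cursor = 0
    for i, (a, b) in enumerate(exon_tr):
        pieces.append(transcript[a:b])
        exon_un.append((cursor, cursor + (b - a)))
        cursor += b - a
        if i < len(introns):
            pieces.append(introns[i])
            cursor += len(introns[i])
    gene_seq = "".join(pieces)
    total = len(gene_seq)
    strand = "-" if rng.random() < config.minus_strand_prob else "+"

    def to_genomic(iv):  # unspliced transcript-sense offsets -> genomic
        a, b = iv
        if strand == "+":
            return (offset + a, offset + b)
        return (offset + total - b, offset + total - a)

    # CDS/UTR intervals: intersect transcript ranges with exons
    def mapped(tr_lo, tr_hi):
        out = []
        for (a, b), (ua, _ub) in zip(exon_tr, exon_un):
            lo, hi = max(a, tr_lo), min(b, tr_hi)
            if lo < hi:
                out.append(to_genomic((ua + lo - a, ua + hi - a)))
        return sorted(out)

    cds_lo, cds_hi = utr5_len, utr5_len + len(cds)
    model = GeneModel(
        gene_id=gene_id, contig=contig, strand=strand,
        start=offset, end=offset + total,
        exons=[to_genomic(iv) for iv in exon_un],
        cds=mapped(cds_lo, cds_hi),
        utr5=mapped(0, cds_lo), utr3=mapped(cds_hi, t_len))
    seq = gene_seq if strand == "+" else reverse_complement(gene_seq)
    return seq, model


def generate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       contig: str = "chr1"):
    """Random genome with planted genes. Returns (genome, genes)."""
    rng = rng or np.random.default_rng(config.seed)
    parts = []
    genes: list[GeneModel] = []
    offset = 0
    for i in range(config.n_genes):
        gap = _random_seq(rng, _u(rng, config.intergenic_length))
        parts.append(gap)
        offset += len(gap)
        seq, model = _build_gene(rng, config, f"gene{i + 1:04d}", contig,
                                 offset)
        parts.append(seq)
        offset += len(seq)
        genes.append(model)
    parts.append(_random_seq(rng, _u(rng, config.intergenic_length)))
    genome = GenomeReference({contig: "".join(parts)})
    return genome, genes


def plant_duplication(genome: GenomeReference, contig: str, center: int,
                      length: int = 201) -> GenomeReference:
    """Append a verbatim copy of the window around ``center`` to the end
    of the contig (separated by random spacer), defeating uniqueness."""
    seq = genome.contigs[contig]
    lo = max(0, center - length // 2)
    hi = min(len(seq), center + length // 2 + 1)
    rng = np.random.default_rng(length)
    spacer = _random_seq(rng, 50)
    return GenomeReference({**genome.contigs,
                            contig: seq + spacer + seq[lo:hi]})


# ---------------------------------------------------------------------------
# editome generation


def _candidate_positions(gene: GeneModel, masked: set,
                         margin: int) -> list[int]:
    """Gene positions excluding homopolymer runs and intron edges."""
    bad = set()
    for s, e in gene.introns:
        bad.update(range(s, min(s + margin, e)))
        bad.update(range(max(e - margin, s), e))
    # keep start/stop codons intact so effect classes stay generic
    if gene.cds:
        cds_pos = gene.spliced_cds_positions()
        bad.update(cds_pos[:3])
        bad.update(cds_pos[-3:])
    return [p for p in range(gene.start, gene.end)
            if p not in bad and (gene.contig, p) not in masked]


def generate_editome(config: SimulationConfig, genes: list[GeneModel],
                     genome: GenomeReference,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ground-truth edit sites with per-condition frequencies.

    Returns a TruthTable DataFrame: contig, position (0-based), gene_id,
    ref, alt (genomic bases), shifted flag, and one ``freq_<condition>``
    column per condition.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    mask = mask_homopolymers(genome, config.homopolymer_min_run)
    masked = set(mask.positions)
    n_host = max(1, int(round(config.hosting_gene_fraction * len(genes))))
    host_idx = rng.choice(len(genes), size=n_host, replace=False)
    hosts = [genes[i] for i in sorted(host_idx)]
    if config.edits_per_gene is not None:
        alloc = {g.gene_id: config.edits_per_gene for g in hosts}
    else:
        draw = rng.multinomial(config.n_edit_sites,
                               np.ones(len(hosts)) / len(hosts))
        alloc = {g.gene_id: int(c) for g, c in zip(hosts, draw)}
    n_shift = int(round(config.shifted_gene_fraction * len(hosts)))
    shifted_genes = set()
    if n_shift:
        shifted_genes = {hosts[i].gene_id for i in
                         rng.choice(len(hosts), size=n_shift, replace=False)}
    rows = []
    lo, hi = config.edit_frequency_range
    for gene in hosts:
        m = alloc[gene.gene_id]
        if m == 0:
            continue
        cand = _candidate_positions(gene, masked, config.intron_edge_margin)
        if len(cand) < m:
            m = len(cand)
        if config.cluster_edits:
            start = int(rng.integers(0, len(cand) - m + 1))
            chosen = cand[start:start + m]
        else:
            chosen = sorted(rng.choice(cand, size=m, replace=False).tolist())
        for pos in chosen:
            ref = genome.base(gene.contig, pos)
            alt = rng.choice([b for b in BASES if b != ref])
            base_f = (config.control_frequency
                      if config.control_frequency is not None
                      else float(rng.uniform(lo, hi)))
            shifted = gene.gene_id in shifted_genes
            freqs = {}
            for cond in config.conditions:
                if shifted and cond in config.shift_conditions:
                    if config.stress_frequency is not None:
                        freqs[cond] = config.stress_frequency
                    else:
                        # push the frequency to the opposite half of range
                        freqs[cond] = float(np.clip(1.0 - base_f, lo, hi))
                else:
                    freqs[cond] = base_f
            rows.append({"contig": gene.contig, "position": pos,
                         "gene_id": gene.gene_id, "ref": ref,
                         "alt": str(alt), "shifted": shifted,
                         **{f"freq_{c}": freqs[c]
                            for c in config.conditions}})
    truth = pd.DataFrame(rows).sort_values(
        ["contig", "position"], ignore_index=True) if rows else pd.DataFrame(
        columns=["contig", "position", "gene_id", "ref", "alt", "shifted"])
    return truth


# ---------------------------------------------------------------------------
# count simulation


def _genic_positions(genes: list[GeneModel]) -> dict[str, np.ndarray]:
    per_contig: dict[str, set] = {}
    for g in genes:
        per_contig.setdefault(g.contig, set()).update(range(g.start, g.end))
    return {c: np.array(sorted(p)) for c, p in per_contig.items()}


def _distribute_errors(rng, source_counts: np.ndarray, source_base: np.ndarray,
                       error_rate: float, out: np.ndarray):
    """Add counts for reads originating as ``source_base``; each read is
    miscalled uniformly to one of the other three bases with probability
    ``error_rate``."""
    for b in range(4):
        sel = np.flatnonzero((source_base == b) & (source_counts > 0))
        if sel.size == 0:
            continue
        pvec = np.full(4, error_rate / 3.0)
        pvec[b] = 1.0 - error_rate
        out[sel] += rng.multinomial(source_counts[sel], pvec)


def simulate_counts(truth: pd.DataFrame, config: SimulationConfig,
                    genome: GenomeReference, genes: list[GeneModel],
                    condition: str, rng: np.random.Generator,
                    coverage_mean: float | None = None,
                    error_rate: float | None = None,
                    edited: bool = True,
                    sample_id: str | None = None) -> SiteCountTable:
    """One sample's per-site base counts over all genic positions.

    At a true edit site with frequency f, edited reads ~ Binomial(n, f);
    every read is then miscalled uniformly to another base with the error
    rate; each read's strand is Bernoulli(fwd_read_prob). With
    ``edited=False`` (DNA-seq) frequencies are all zero.
    """
    mean = coverage_mean if coverage_mean is not None else config.coverage_mean
    err = error_rate if error_rate is not None else config.error_rate
    size = config.coverage_dispersion
    parts = []
    genic = _genic_positions(genes)
    for contig, pos in genic.items():
        P = len(pos)
        ref = np.array([genome.base(contig, int(p)) for p in pos])
        ref_idx = np.array([BASE_INDEX[b] for b in ref])
        n = rng.negative_binomial(size, size / (size + mean), P)
        f = np.zeros(P)
        alt_idx = ref_idx.copy()
        if edited and len(truth):
            tsub = truth[truth.contig == contig]
            pos_to_row = {int(p): i for i, p in enumerate(pos)}
            for _, t in tsub.iterrows():
                i = pos_to_row.get(int(t.position))
                if i is None:
                    continue
                f[i] = t[f"freq_{condition}"]
                alt_idx[i] = BASE_INDEX[t.alt]
        k_edit = rng.binomial(n, f)
        n_ref = n - k_edit
        base_counts = np.zeros((P, 4), dtype=np.int64)
        _distribute_errors(rng, n_ref, ref_idx, err, base_counts)
        _distribute_errors(rng, k_edit, alt_idx, err, base_counts)
        fwd = rng.binomial(base_counts, config.fwd_read_prob)
        counts = np.stack([fwd, base_counts - fwd], axis=2)
        parts.append((np.full(P, contig, dtype=object), pos, ref, counts))
    contig_arr = np.concatenate([p[0] for p in parts])
    pos_arr = np.concatenate([p[1] for p in parts])
    ref_arr = np.concatenate([p[2] for p in parts])
    counts_arr = np.concatenate([p[3] for p in parts])
    return SiteCountTable(contig_arr, pos_arr, ref_arr, counts_arr,
                          sample_id=sample_id)


def generate_bundle(config: SimulationConfig) -> SimulationBundle:
    """Full synthetic dataset: reference, editome, one RNA count table per
    (condition, replicate) and one DNA count table."""
    rng = np.random.default_rng(config.seed)
    genome, genes = generate_reference(config, rng)
    truth = generate_editome(config, genes, genome, rng)
    if config.duplication and len(truth):
        center = int(truth.iloc[0].position)
        genome = plant_duplication(genome, truth.iloc[0].contig, center)
    bundle = SimulationBundle(config, genome, genes, truth)
    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            bundle.rna_tables[(cond, f"r{rep}")] = simulate_counts(
                truth, config, genome, genes, cond, rng,
                sample_id=f"{cond}_r{rep}")
    bundle.dna_table = simulate_counts(
        truth, config, genome, genes, config.conditions[0], rng,
        coverage_mean=config.dna_coverage_mean,
        error_rate=config.dna_error_rate, edited=False, sample_id="dna")
    return bundle


# ---------------------------------------------------------------------------
# writers (text formats only)


def write_fasta(genome: GenomeReference, path, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff(genes: list[GeneModel], path, source: str = "editome-sim"):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            def line(ftype, s, e, attrs, phase="."):
                fh.write("\t".join([
                    g.contig, source, ftype, str(s + 1), str(e), ".",
                    g.strand, phase, attrs]) + "\n")
            line("gene", g.start, g.end, f"ID={g.gene_id}")
            mrna = f"{g.gene_id}.t1"
            line("mRNA", g.start, g.end, f"ID={mrna};Parent={g.gene_id}")
            for i, (s, e) in enumerate(g.exons, 1):
                line("exon", s, e, f"ID={mrna}.exon{i};Parent={mrna}")
            cds_iv = g.cds if g.strand == "+" else g.cds[::-1]
            phase = 0
            for i, (s, e) in enumerate(cds_iv, 1):
                line("CDS", s, e, f"ID={mrna}.cds;Parent={mrna}",
                     phase=str(phase))
            # running phase for the next CDS segment
                phase = (3 - ((e - s) - phase) % 3) % 3
            for s, e in g.utr5:
                line("five_prime_UTR", s, e, f"Parent={mrna}")
            for s, e in g.utr3:
                line("three_prime_UTR", s, e, f"Parent={mrna}")


def write_truth(truth: pd.DataFrame, path):
    out = truth.copy()
    if len(out):
        out["position"] = out["position"] + 1  # 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def write_bundle(bundle: SimulationBundle, outdir):
    """Write the whole bundle as plain-text files under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(bundle.genome, os.path.join(outdir, "genome.fa"))
    write_gff(bundle.genes, os.path.join(outdir, "genes.gff3"))
    write_truth(bundle.truth, os.path.join(outdir, "truth.tsv"))
    manifest = []
    for (cond, rep), table in bundle.rna_tables.items():
        name = f"counts_{cond}_{rep}.tsv"
        table.to_tsv(os.path.join(outdir, name))
        manifest.append({"path": name, "condition": cond, "replicate": rep})
    if bundle.dna_table is not None:
        bundle.dna_table.to_tsv(os.path.join(outdir, "dna_counts.tsv"))
    pd.DataFrame(manifest).to_csv(
        os.path.join(outdir, "samples.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM helpers (round-trip oracle for the pileup module)


def sam_text(reads, genome: GenomeReference) -> str:
    """Render simple read dicts as SAM text.

    Each read: {qname, contig, pos (0-based), seq, reverse: bool,
    mapq: int, nh: int (optional), paired: bool, mate_pos}.
    """
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, seq in genome.contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    for r in reads:
        flag = 0
        if r.get("reverse"):
            flag |= 16
        mate_pos = r.get("mate_pos")
        if r.get("paired"):
            flag |= 1 | 2 | (64 if r.get("first", True) else 128)
            if r.get("mate_reverse"):
                flag |= 32
        rnext = "=" if mate_pos is not None else "*"
        pnext = (mate_pos + 1) if mate_pos is not None else 0
        seq = r["seq"]
        fields = [r["qname"], str(flag), r["contig"], str(r["pos"] + 1),
                  str(r.get("mapq", 60)), f"{len(seq)}M", rnext, str(pnext),
                  "0", seq, "*"]
        if "nh" in r:
            fields.append(f"NH:i:{r['nh']}")
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def random_reads(genome: GenomeReference, n: int, read_len: int,
                 rng: np.random.Generator, error_rate: float = 0.0):
    """Uniformly placed perfect-match reads with optional uniform
    miscalls; used by round-trip tests of the pileup contract."""
    reads = []
    for i in range(n):
        contig = list(genome.contigs)[rng.integers(len(genome.contigs))]
        L = genome.length(contig)
        pos = int(rng.integers(0, L - read_len + 1))
        seq = list(genome.slice(contig, pos, pos + read_len))
        for j in range(read_len):
            if error_rate and rng.random() < error_rate:
                seq[j] = str(rng.choice([b for b in BASES if b != seq[j]]))
        reads.append({"qname": f"read{i}", "contig": contig, "pos": pos,
                      "seq": "".join(seq),
                      "reverse": bool(rng.random() < 0.5)})
    return reads
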