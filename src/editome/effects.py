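"""Variant effect annotation of edits against gene models, plus the
downstream contingency, amino-acid-change and delta-shift analyses.

Effect classes follow the usual substitution-annotator vocabulary:
5' UTR, gain/loss of start codon, synonymous/non-synonymous coding,
intron, gain/loss of stop codon, 3' UTR. The standard genetic code is
used throughout (nuclear genes only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import fisher_exact, ttest_ind

from editome.calling import bh_adjust
from editome.reference import GeneModel, GenomeReference, complement

EFFECT_CLASSES = (
    "5' UTR",
    "Gain of start codon",
    "Loss of start codon",
    "Synonymous coding",
    "Non-synonymous coding",
    "Intron",
    "Gain of stop codon",
    "Loss of stop codon",
    "3' UTR",
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class EffectAnnotation:
    contig: str
    position: int  # 0-based genomic
    gene_id: str
    ref: str  # transcript-sense
    alt: str  # transcript-sense
    effect: str
    codon_before: str | None = None
    codon_after: str | None = None
    aa_before: str | None = None
    aa_after: str | None = None
    protein_position: int | None = None  # 1-based codon index

    @property
    def edit_type(self) -> str:
        return f"{self.ref}-to-{self.alt}"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_effect(contig: str, position: int, ref: str, alt: str,
                    gene: GeneModel, genome: GenomeReference
                    ) -> EffectAnnotation:
    """Classify one (edit, allele, gene) triple.

    ``ref``/``alt`` are genomic-strand bases; the annotation reports them
    in transcript sense. Stop-codon classes take precedence over
    (non-)synonymous; start classes apply only at the annotated start
    codon. The caller must pre-assign the gene (position inside the gene
    span) and only pass genes with a valid CDS for coding classes.
    """
    if not gene.contains(position):
        raise ValueError(f"position {position} outside gene {gene.gene_id}")
    if genome.base(contig, position) != ref:
        raise ValueError(f"{contig}:{position}: ref {ref!r} disagrees with "
                         f"genome {genome.base(contig, position)!r}")
    t_ref = ref if gene.strand == "+" else complement(ref)
    t_alt = alt if gene.strand == "+" else complement(alt)
    base = dict(contig=contig, position=position, gene_id=gene.gene_id,
                ref=t_ref, alt=t_alt)
    if gene.is_intronic(position):
        return EffectAnnotation(effect="Intron", **base)
    if not gene.cds or not gene.cds_valid:
        raise ValueError(
            f"gene {gene.gene_id} has no valid CDS; cannot annotate exonic "
            "effects")
    if gene.is_cds(position):
        off = gene.cds_offset(position)
        cds_seq = gene.spliced_cds_sequence(genome)
        codon_i, within = divmod(off, 3)
        codon_before = cds_seq[codon_i * 3: codon_i * 3 + 3]
        assert codon_before[within] == t_ref
        codon_after = (codon_before[:within] + t_alt
                       + codon_before[within + 1:])
        aa_before = _translate(codon_before)
        aa_after = _translate(codon_after)
        coding = dict(codon_before=codon_before, codon_after=codon_after,
                      aa_before=aa_before, aa_after=aa_after,
                      protein_position=codon_i + 1)
        if codon_i == 0 and codon_before == "ATG" and codon_after != "ATG":
            effect = "Loss of start codon"
        elif codon_i == 0 and codon_after == "ATG" and codon_before != "ATG":
            effect = "Gain of start codon"
        elif aa_after == "*" and aa_before != "*":
            effect = "Gain of stop codon"
        elif aa_before == "*" and aa_after != "*":
            effect = "Loss of stop codon"
        elif aa_before == aa_after:
            effect = "Synonymous coding"
        else:
            effect = "Non-synonymous coding"
        return EffectAnnotation(effect=effect, **base, **coding)
    # exonic, non-CDS -> UTR side in transcript sense
    if any(s <= position < e for s, e in gene.utr5):
        return EffectAnnotation(effect="5' UTR", **base)
    if any(s <= position < e for s, e in gene.utr3):
        return EffectAnnotation(effect="3' UTR", **base)
    raise ValueError(
        f"position {position} in gene {gene.gene_id} is exonic but neither "
        "CDS nor UTR")


def annotate_sites(sites, gene_index, genome) -> list[EffectAnnotation]:
    """Annotate every (site, alt allele) pair assigned to a gene with a
    valid CDS; one annotation per allele (multi-edit sites yield several).
    """
    out: list[EffectAnnotation] = []
    for site in sites:
        gene = gene_index.assign(site.contig, site.position)
        if gene is None or (gene.exons and not gene.cds):
            continue
        if not gene.cds_valid:
            continue
        for alt in site.alts:
            try:
                out.append(annotate_effect(site.contig, site.position,
                                           site.ref, alt, gene, genome))
            except ValueError:
                continue
    return out


# ---------------------------------------------------------------------------
# contingency analysis (subset of edits vs background of all genic edits)


def count_effects(annotations) -> dict[str, int]:
    counts = dict.fromkeys(EFFECT_CLASSES, 0)
    for a in annotations:
        counts[a.effect] += 1
    return counts


def contingency_from_counts(subset_counts: dict[str, int],
                            background_counts: dict[str, int],
                            classes=EFFECT_CLASSES) -> pd.DataFrame:
    """Per-class 2x2 Fisher's exact test (two-sided) of class count vs
    remainder of the column total, subset vs background, BH-adjusted
    across the classes."""
    sub_total = sum(subset_counts.get(c, 0) for c in classes)
    bg_total = sum(background_counts.get(c, 0) for c in classes)
    rows = []
    for cls in classes:
        a = subset_counts.get(cls, 0)
        b = background_counts.get(cls, 0)
        if a == 0 and b == 0:
            p = 1.0
        else:
            _, p = fisher_exact([[a, sub_total - a], [b, bg_total - b]],
                                alternative="two-sided")
        rows.append({"effect": cls, "subset_count": a,
                     "subset_pct": a / sub_total if sub_total else 0.0,
                     "background_count": b,
                     "background_pct": b / bg_total if bg_total else 0.0,
                     "pvalue": p})
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    return df


def effect_contingency_tests(subset_annotations,
                             background_annotations) -> pd.DataFrame:
    return contingency_from_counts(count_effects(subset_annotations),
                                   count_effects(background_annotations))


# ---------------------------------------------------------------------------
# amino-acid change matrix


def aa_change_matrix(annotations) -> pd.DataFrame:
    """20x20 counts of (original AA -> edited AA) for non-synonymous
    annotations; the diagonal is zero by construction."""
    mat = pd.DataFrame(0, index=list(AA_ALPHABET), columns=list(AA_ALPHABET))
    for a in annotations:
        if a.effect != "Non-synonymous coding":
            continue
        if a.aa_before in mat.index and a.aa_after in mat.columns:
            mat.loc[a.aa_before, a.aa_after] += 1
    return mat


# ---------------------------------------------------------------------------
# delta shifts


def delta_shifts(sites, sample_tables, contrast: tuple[str, str]
                 ) -> dict[tuple[str, int], float]:
    """|mean stress frequency - mean control frequency| per site, with
    per-replicate frequencies computed from the sample count tables;
    replicates without coverage at a site are skipped."""
    from editome.pileup import BASE_INDEX

    stress, control = contrast
    out: dict[tuple[str, int], float] = {}
    for site in sites:
        alt_idx = [BASE_INDEX[a] for a in site.alts]
        freqs: dict[str, list[float]] = {stress: [], control: []}
        for (condition, _rep), table in sample_tables.items():
            if condition not in freqs:
                continue
            i = table.row(site.contig, site.position)
            if i is None or table.n[i] == 0:
                continue
            freqs[condition].append(
                float(table.base_counts[i, alt_idx].sum() / table.n[i]))
        if freqs[stress] and freqs[control]:
            out[(site.contig, site.position)] = abs(
                float(np.mean(freqs[stress])) -
                float(np.mean(freqs[control])))
    return out


def delta_shift_comparison(nonsyn_deltas, syn_deltas) -> dict:
    """Welch two-sample two-tailed t-test of non-synonymous vs synonymous
    delta shifts. Both groups need >= 2 members."""
    a = np.asarray(list(nonsyn_deltas), dtype=float)
    b = np.asarray(list(syn_deltas), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 delta values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        stat, p = ttest_ind(a, b, equal_var=False)
    return {"nonsyn_mean": float(a.mean()), "syn_mean": float(b.mean()),
            "nonsyn_n": len(a), "syn_n": len(b),
            "statistic": float(stat), "pvalue": float(p)}
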