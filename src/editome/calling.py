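"""Significantly edited site calling from pooled base counts.

Editing errors at a site with coverage n are modelled as Binomial(n, p)
with p the maximum per-base sequencing error rate (default 0.01, Phred 20).
The p-value of a site with k non-reference reads is the probability of
observing at least k miscalls; p-values are Benjamini-Hochberg corrected
over all candidate sites and called significant below a corrected-p
threshold (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from editome.pileup import BASES, BASE_INDEX, SiteCountTable


@dataclass(frozen=True)
class EditCallConfig:
    error_rate: float = 0.01
    significance: float = 0.01  # threshold on BH-corrected p
    multi_edit_min_frequency: float = 0.20  # overall f for multi-allelic call
    multi_edit_min_reads: int = 2  # per-allele read support
    family: str = "candidates"  # BH family: "candidates" | "all_covered"

    def __post_init__(self):
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must be in (0, 1)")
        if not 0 < self.significance < 1:
            raise ValueError("significance must be in (0, 1)")
        if not 0 < self.multi_edit_min_frequency < 1:
            raise ValueError("multi_edit_min_frequency must be in (0, 1)")
        if self.multi_edit_min_reads < 1:
            raise ValueError("multi_edit_min_reads must be >= 1")
        if self.family not in ("candidates", "all_covered"):
            raise ValueError("family must be 'candidates' or 'all_covered'")


@dataclass
class EditSite:
    """A called candidate edit site (positions 0-based internally)."""

    contig: str
    position: int
    ref: str
    alts: tuple[str, ...]
    alt_counts: tuple[int, ...]
    n: int  # total coverage
    k: int  # reads supporting the reported alt allele(s)
    pvalue: float
    qvalue: float
    significant: bool
    strand_support: tuple[int, int]  # (fwd, rev) reads of reported alts
    has_strand: bool = True
    flags: dict = field(default_factory=dict)

    @property
    def frequency(self) -> float:
        return self.k / self.n if self.n else 0.0

    @property
    def is_multi(self) -> bool:
        return len(self.alts) > 1

    @property
    def primary_alt(self) -> str:
        return self.alts[0]


def edit_pvalue(k: int, n: int, p: float = 0.01) -> float:
    """Upper-tail probability P(X >= k) for X ~ Binomial(n, p)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(binom.sf(k - 1, n, p))


def edit_pvalues(k: np.ndarray, n: np.ndarray, p: float = 0.01) -> np.ndarray:
    """Vectorised :func:`edit_pvalue`."""
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k > n) or np.any(k < 0) or np.any(n < 1):
        raise ValueError("need 0 <= k <= n and n >= 1")
    return binom.sf(k - 1, n, p)


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` optionally sets the size of the testing family (>= len(pvalues));
    omitted hypotheses are implicitly p = 1, which never changes the
    adjustment of the supplied values beyond the m/i scaling.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    elif m < p.size:
        raise ValueError("family size m cannot be smaller than len(pvalues)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _resolve_alleles(base_counts: np.ndarray, ref_idx: int, n: int,
                     config: EditCallConfig):
    """Post-significance allele assignment.

    Returns (alts, alt_counts, k). If >= 2 distinct alt bases each reach the
    per-allele read minimum AND the overall non-reference frequency reaches
    the multi-edit threshold, the site is multi-allelic and k sums the
    qualifying alleles; otherwise only the majority alt base is reported and
    minority-alt reads stay in n but not in k.
    """
    alt_idx = [i for i in range(4) if i != ref_idx and base_counts[i] > 0]
    k_total = int(sum(base_counts[i] for i in alt_idx))
    qualifying = [i for i in alt_idx
                  if base_counts[i] >= config.multi_edit_min_reads]
    if (len(qualifying) >= 2
            and k_total / n >= config.multi_edit_min_frequency):
        chosen = sorted(qualifying, key=lambda i: (-base_counts[i], BASES[i]))
    else:
        # majority allele; deterministic tie-break by base order
        chosen = [max(alt_idx, key=lambda i: (base_counts[i], -i))] \
            if alt_idx else []
        chosen = sorted(chosen)
    alts = tuple(BASES[i] for i in chosen)
    alt_counts = tuple(int(base_counts[i]) for i in chosen)
    return alts, alt_counts, int(sum(alt_counts))


def call_edits(table: SiteCountTable,
               config: EditCallConfig | None = None) -> list[EditSite]:
    """Call edit sites on a (pooled) count table.

    Candidates are covered positions with at least one non-reference read;
    the significance test uses k = ALL non-reference reads (the error model
    concerns any miscall); allele assignment happens afterwards.
    Iteration order is (contig, position) ascending so q-values are
    reproducible.
    """
    config = config or EditCallConfig()
    if len(table) == 0:
        return []
    n = table.n
    bc = table.base_counts  # (sites, 4)
    ref_idx = np.array([BASE_INDEX.get(r, -1) for r in table.ref])
    if np.any(ref_idx < 0):
        bad = np.flatnonzero(ref_idx < 0)[0]
        raise ValueError(f"non-ACGT reference base {table.ref[bad]!r} at "
                         f"{table.contig[bad]}:{table.pos[bad] + 1}")
    ref_count = bc[np.arange(len(table)), ref_idx]
    k_total = n - ref_count
    covered = n > 0
    cand = covered & (k_total >= 1)
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return []
    pvals = edit_pvalues(k_total[idx], n[idx], config.error_rate)
    m = int(covered.sum()) if config.family == "all_covered" else None
    qvals = bh_adjust(pvals, m=m)
    sites: list[EditSite] = []
    for j, i in enumerate(idx):
        alts, alt_counts, k = _resolve_alleles(
            bc[i], int(ref_idx[i]), int(n[i]), config)
        chosen_idx = [BASE_INDEX[a] for a in alts]
        fwd = int(table.counts[i, chosen_idx, 0].sum())
        rev = int(table.counts[i, chosen_idx, 1].sum())
        sites.append(EditSite(
            contig=str(table.contig[i]), position=int(table.pos[i]),
            ref=str(table.ref[i]), alts=alts, alt_counts=alt_counts,
            n=int(n[i]), k=k, pvalue=float(pvals[j]), qvalue=float(qvals[j]),
            significant=bool(qvals[j] < config.significance),
            strand_support=(fwd, rev), has_strand=table.has_strand))
    return sites


def sites_to_dataframe(sites: list[EditSite]):
    """Tabular export of called sites (1-based positions on disk)."""
    import pandas as pd

    rows = []
    for s in sites:
        rows.append({
            "contig": s.contig, "position": s.position + 1, "ref": s.ref,
            "alt": ",".join(s.alts),
            "alt_counts": ",".join(map(str, s.alt_counts)),
            "n": s.n, "k": s.k, "frequency": s.frequency,
            "pvalue": s.pvalue, "qvalue": s.qvalue,
            "significant": s.significant,
            "fwd_support": s.strand_support[0],
            "rev_support": s.strand_support[1],
            **{f"filter_{k}": v for k, v in s.flags.items()},
        })
    return pd.DataFrame(rows)


def sites_from_dataframe(df) -> list[EditSite]:
    """Inverse of :func:`sites_to_dataframe` (flags columns optional)."""
    sites = []
    flag_cols = [c for c in df.columns if c.startswith("filter_")]
    for _, r in df.iterrows():
        alts = tuple(str(r["alt"]).split(","))
        alt_counts = tuple(int(x) for x in str(r["alt_counts"]).split(","))
        sites.append(EditSite(
            contig=str(r["contig"]), position=int(r["position"]) - 1,
            ref=str(r["ref"]), alts=alts, alt_counts=alt_counts,
            n=int(r["n"]), k=int(r["k"]), pvalue=float(r["pvalue"]),
            qvalue=float(r["qvalue"]), significant=bool(r["significant"]),
            strand_support=(int(r["fwd_support"]), int(r["rev_support"])),
            flags={c[len("filter_"):]: r[c] for c in flag_cols}))
    return sites
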