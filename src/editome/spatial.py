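"""Positional distribution of genic edits and the neighbour-distance
clustering test.

Distances are measured in genomic bases between edit coordinates within a
gene. The clustering null is built by re-placing each gene's edits
uniformly at random (without replacement) over the gene's positions,
recomputing neighbour distances, and averaging histograms over the
configured number of shuffles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest, chi2

from editome.reference import GeneIndex, GeneModel


def assign_edits(sites, gene_index: GeneIndex) -> dict[str, list[int]]:
    """Group genic edit positions by their assigned gene (sorted)."""
    by_gene: dict[str, list[int]] = {}
    for s in sites:
        gene = gene_index.assign(s.contig, s.position)
        if gene is not None:
            by_gene.setdefault(gene.gene_id, []).append(s.position)
    for positions in by_gene.values():
        positions.sort()
    return by_gene


# ---------------------------------------------------------------------------
# positional histograms


@dataclass
class PositionalHistogram:
    feature_class: str  # gene | exon | intron
    bin_width: float
    counts: np.ndarray
    relative_positions: list[float] = field(default_factory=list)

    @property
    def n_edits(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self):
        import pandas as pd
        edges = np.arange(len(self.counts) + 1) * self.bin_width
        return pd.DataFrame({
            "bin_start": edges[:-1], "bin_end": np.minimum(edges[1:], 1.0),
            "count": self.counts})


def _feature_relative_position(pos: int, gene: GeneModel,
                               feature_class: str) -> float | None:
    """Length-normalised transcript-sense position, or None when the edit
    does not fall in the requested feature class."""
    if feature_class == "gene":
        length = gene.span_length
        off = gene.gene_offset(pos)
    else:
        intervals = gene.exons if feature_class == "exon" else gene.introns
        hit = next(((s, e) for s, e in intervals if s <= pos < e), None)
        if hit is None:
            return None
        s, e = hit
        length = e - s
        off = (pos - s) if gene.strand == "+" else (e - 1 - pos)
    if length <= 1:
        return 0.0
    return off / (length - 1)


def relative_positions(edits_by_gene: dict[str, list[int]],
                       genes: dict[str, GeneModel],
                       feature_class: str = "gene",
                       bin_width: float = 0.025) -> PositionalHistogram:
    """Tally edits along the normalised length of genes, exons or introns."""
    if feature_class not in ("gene", "exon", "intron"):
        raise ValueError("feature_class must be gene, exon or intron")
    n_bins = int(np.ceil(1.0 / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    rels: list[float] = []
    for gene_id, positions in edits_by_gene.items():
        gene = genes[gene_id]
        for pos in positions:
            rel = _feature_relative_position(pos, gene, feature_class)
            if rel is None:
                continue
            rels.append(rel)
            counts[min(int(rel / bin_width), n_bins - 1)] += 1
    return PositionalHistogram(feature_class, bin_width, counts, rels)


def five_prime_enrichment_test(relative_pos, cutoff: float = 0.05) -> float:
    """One-sided upper-tail binomial test of the fraction of edits in the
    initial ``cutoff`` of the normalised length against null = cutoff."""
    rels = np.asarray(relative_pos, dtype=float)
    n = rels.size
    if n == 0:
        raise ValueError("no edits to test")
    k = int((rels < cutoff).sum())
    return float(binomtest(k, n, cutoff, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# neighbour distances and the Monte-Carlo clustering test


def neighbor_distances(edits_by_gene: dict[str, list[int]]) -> list[float]:
    """One value per edit in genes with >= 2 edits: interior edits
    contribute the mean of their two flanking gaps, terminal edits their
    single flanking gap."""
    out: list[float] = []
    for positions in edits_by_gene.values():
        out.extend(_distances_one_gene(np.asarray(sorted(positions))))
    return out


def _distances_one_gene(pos: np.ndarray) -> list[float]:
    m = len(pos)
    if m < 2:
        return []
    gaps = np.diff(pos).astype(float)
    values = [gaps[0]]
    values.extend((gaps[:-1] + gaps[1:]) / 2.0)
    values.append(gaps[-1])
    return values


@dataclass
class ClusteringTestResult:
    observed: np.ndarray  # unit-distance histogram
    expected: np.ndarray  # Monte-Carlo mean, unit-distance
    n_shuffles: int
    seed: int
    chi2_statistic: float
    df: int
    pvalue: float
    pooled_observed: np.ndarray
    pooled_expected: np.ndarray
    binning: dict

    def metadata(self) -> dict:
        return {"n_shuffles": self.n_shuffles, "seed": self.seed,
                "chi2": self.chi2_statistic, "df": self.df,
                "pvalue": self.pvalue, **self.binning}

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def _null_histogram_one_gene(m: int, L: int, n_shuffles: int,
                             rng: np.random.Generator, acc: np.ndarray,
                             allowed: np.ndarray | None = None):
    """Accumulate the unit-binned distance histogram of ``n_shuffles``
    uniform placements of m edits over L positions into ``acc``."""
    domain = L if allowed is None else len(allowed)
    if m > domain:
        raise ValueError("more edits than available positions")
    chunk = max(1, int(4_000_000 / max(domain, 1)))
    done = 0
    while done < n_shuffles:
        s = min(chunk, n_shuffles - done)
        r = rng.random((s, domain))
        idx = np.argpartition(r, m - 1, axis=1)[:, :m]
        pos = np.sort(idx if allowed is None else allowed[idx], axis=1)
        gaps = np.diff(pos, axis=1).astype(float)
        vals = [gaps[:, 0], gaps[:, -1]]
        if m > 2:
            vals.append(((gaps[:, :-1] + gaps[:, 1:]) / 2.0).ravel())
        v = np.floor(np.concatenate(vals)).astype(np.int64)
        acc += np.bincount(v, minlength=len(acc))
        done += s
    # conservation: every shuffle contributes exactly m values per gene


def _pool_bins(obs: np.ndarray, exp: np.ndarray, min_expected: float = 10.0):
    """Left-to-right pooling until every pooled bin's expected count is at
    least ``min_expected``; a deficient tail is merged into the last bin."""
    obs_p, exp_p = [], []
    co = ce = 0.0
    for o, e in zip(obs, exp):
        co += o
        ce += e
        if ce >= min_expected:
            obs_p.append(co)
            exp_p.append(ce)
            co = ce = 0.0
    if (co or ce):
        if obs_p:
            obs_p[-1] += co
            exp_p[-1] += ce
        else:
            obs_p, exp_p = [co], [ce]
    return np.asarray(obs_p), np.asarray(exp_p)


def clustering_test(edits_by_gene: dict[str, list[int]],
                    gene_lengths: dict[str, int],
                    n_shuffles: int = 10_000, seed: int = 0,
                    allowed_positions: dict[str, np.ndarray] | None = None,
                    percentile: float = 99.0,
                    min_expected: float = 10.0) -> ClusteringTestResult:
    """Monte-Carlo neighbour-distance clustering test.

    Per shuffle, each gene's edits are re-placed uniformly at random
    without replacement over the gene's positions (optionally restricted to
    ``allowed_positions``, e.g. exonic offsets); the expected distribution
    is the mean histogram over shuffles. A chi-square statistic compares
    observed and expected counts over unit-distance bins up to the stated
    percentile of the pooled mass (remainder pooled), after merging bins so
    every expected count reaches ``min_expected``; p is taken from the
    chi-square distribution with (bins - 1) degrees of freedom.

    ``min_expected`` defaults to 10 rather than the textbook 5: per-edit
    distance values within a gene are positively correlated (neighbouring
    edits share a gap), and sparse bins turn that correlation into mild
    type-I inflation; pooling to expected >= 10 restores 0.05 calibration
    in null simulations.
    """
    contributing = {g: sorted(p) for g, p in edits_by_gene.items()
                    if len(p) >= 2}
    if not contributing:
        raise ValueError("no gene with >= 2 edits")
    max_len = max(gene_lengths[g] for g in contributing)
    observed = np.zeros(max_len + 1, dtype=np.int64)
    for g, positions in contributing.items():
        v = np.floor(_distances_one_gene(np.asarray(positions))).astype(int)
        observed += np.bincount(v, minlength=len(observed))
    rng = np.random.default_rng(seed)
    null_acc = np.zeros(max_len + 1, dtype=np.int64)
    for g in sorted(contributing):
        m = len(contributing[g])
        allowed = None if allowed_positions is None \
            else np.asarray(sorted(allowed_positions[g]))
        _null_histogram_one_gene(m, gene_lengths[g], n_shuffles, rng,
                                 null_acc, allowed)
    expected = null_acc / n_shuffles
    total = observed.sum()
    if not np.isclose(expected.sum(), total):
        raise AssertionError("shuffles did not conserve per-gene edit counts")
    # binning: unit bins up to the percentile of the pooled mass
    pooled_mass = observed + expected
    cum = np.cumsum(pooled_mass) / pooled_mass.sum()
    d_hi = int(np.searchsorted(cum, percentile / 100.0))
    d_hi = max(d_hi, 1)
    obs_b = np.append(observed[:d_hi].astype(float), observed[d_hi:].sum())
    exp_b = np.append(expected[:d_hi], expected[d_hi:].sum())
    # scale expected exactly onto the observed total before pooling
    exp_b *= total / exp_b.sum()
    obs_p, exp_p = _pool_bins(obs_b, exp_b, min_expected)
    stat = float(((obs_p - exp_p) ** 2 / exp_p).sum())
    df = max(len(obs_p) - 1, 1)
    pvalue = float(chi2.sf(stat, df))
    return ClusteringTestResult(
        observed=observed, expected=expected, n_shuffles=n_shuffles,
        seed=seed, chi2_statistic=stat, df=df, pvalue=pvalue,
        pooled_observed=obs_p, pooled_expected=exp_p,
        binning={"unit_bins_up_to": d_hi, "percentile": percentile,
                 "min_expected": min_expected, "n_pooled_bins": len(obs_p)})
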