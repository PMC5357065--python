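"""Per-gene binomial GLM test of condition-specific differential editing.

For each gene and each stress-vs-control contrast, a binomial-family GLM
with logit link is fitted on replicate x position cells (two-column
response: edited, unedited reads). The full model contains a condition
main effect, a position factor and their interaction; the reduced model
contains the position factor only. The likelihood-ratio (analysis of
deviance) statistic is referred to a chi-square distribution, and p-values
are BH-corrected across all tested genes per contrast. Replicate rows are
never pooled, so replicates carry equal weight regardless of depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from editome.calling import EditSite, bh_adjust
from editome.pileup import BASE_INDEX, SiteCountTable
from editome.reference import GeneIndex

logger = logging.getLogger(__name__)

_MAXITER = 25
_TOL = 1e-8
_SEPARATION_BOUND = 30.0  # |logit| beyond this -> treated as separation


@dataclass
class GeneEditProfile:
    """Replicate x position edited/unedited read counts for one gene.

    ``cells`` columns: condition, replicate, position, edited, unedited.
    Positions with zero coverage in a replicate are missing rows, not
    zero rows.
    """

    gene_id: str
    positions: list[int]
    cells: pd.DataFrame

    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class DifferentialEditingResult:
    gene_id: str
    contrast: tuple[str, str]  # (stress, control)
    statistic: float
    df: int
    pvalue: float
    qvalue: float = float("nan")
    n_positions: int = 0
    n_replicates: dict = field(default_factory=dict)
    mean_shift: dict = field(default_factory=dict)  # position -> freq shift
    ok: bool = True  # False on non-convergence / separation

    @property
    def significant(self) -> bool:
        return self.ok and self.qvalue < 0.05


def build_gene_profiles(sites: list[EditSite],
                        sample_tables: dict[tuple[str, str], SiteCountTable],
                        gene_index: GeneIndex) -> dict[str, GeneEditProfile]:
    """Assemble per-gene profiles from called+filtered sites and
    per-sample count tables keyed by (condition, replicate)."""
    by_gene: dict[str, list[EditSite]] = {}
    for s in sites:
        gene = gene_index.assign(s.contig, s.position)
        if gene is None:
            continue  # intergenic edits have no profile
        by_gene.setdefault(gene.gene_id, []).append(s)
    profiles: dict[str, GeneEditProfile] = {}
    for gene_id, gene_sites in by_gene.items():
        rows = []
        for site in sorted(gene_sites, key=lambda s: s.position):
            alt_idx = [BASE_INDEX[a] for a in site.alts]
            for (condition, replicate), table in sample_tables.items():
                i = table.row(site.contig, site.position)
                if i is None:
                    continue
                n = int(table.n[i])
                if n == 0:
                    continue  # missing, not zero
                edited = int(table.base_counts[i, alt_idx].sum())
                rows.append({"condition": condition, "replicate": replicate,
                             "position": site.position,
                             "edited": edited, "unedited": n - edited})
        if rows:
            cells = pd.DataFrame(rows)
            profiles[gene_id] = GeneEditProfile(
                gene_id, sorted(cells["position"].unique()), cells)
    return profiles


def filter_testable_genes(profiles: dict[str, GeneEditProfile],
                          contrast: tuple[str, str],
                          min_positions: int = 2, min_coverage: int = 1,
                          replicates: dict[str, list] | None = None
                          ) -> dict[str, GeneEditProfile]:
    """Keep genes with >= ``min_positions`` positions covered with at
    least ``min_coverage`` reads in every replicate of both conditions of
    the contrast. The replicate roster defaults to the union observed
    across all profiles."""
    if replicates is None:
        replicates = {}
        for prof in profiles.values():
            for cond, rep in zip(prof.cells["condition"],
                                 prof.cells["replicate"]):
                replicates.setdefault(cond, set()).add(rep)
        replicates = {c: sorted(r) for c, r in replicates.items()}
    needed = [(c, r) for c in contrast for r in replicates.get(c, [])]
    kept: dict[str, GeneEditProfile] = {}
    for gene_id, prof in profiles.items():
        cells = prof.cells
        ok_positions = 0
        for pos in prof.positions:
            sub = cells[cells["position"] == pos]
            covered = {(c, r) for c, r, e, u
                       in zip(sub["condition"], sub["replicate"],
                              sub["edited"], sub["unedited"])
                       if e + u >= min_coverage}
            if all(key in covered for key in needed):
                ok_positions += 1
        if ok_positions >= min_positions:
            kept[gene_id] = prof
    return kept


def _design_matrices(cells: pd.DataFrame, contrast: tuple[str, str]):
    """Full (condition + position + interaction) and reduced (position
    only) design matrices; treatment coding with control as baseline."""
    stress, control = contrast
    cond = (cells["condition"] == stress).to_numpy(float)
    pos = pd.get_dummies(cells["position"].astype("category"),
                         drop_first=True, dtype=float)
    intercept = np.ones((len(cells), 1))
    x_red = np.hstack([intercept, pos.to_numpy()])
    inter = pos.to_numpy() * cond[:, None]
    x_full = np.hstack([intercept, cond[:, None], pos.to_numpy(), inter])
    return x_full, x_red


def fit_differential_glm(profile: GeneEditProfile,
                         contrast: tuple[str, str]
                         ) -> DifferentialEditingResult:
    """Analysis-of-deviance LRT of condition + condition x position
    (jointly) against position-only for one gene."""
    stress, control = contrast
    cells = profile.cells[profile.cells["condition"].isin(contrast)]
    result = DifferentialEditingResult(
        gene_id=profile.gene_id, contrast=contrast, statistic=0.0, df=0,
        pvalue=1.0, n_positions=len(cells["position"].unique()),
        n_replicates={c: cells[cells["condition"] == c]["replicate"].nunique()
                      for c in contrast})
    if cells.empty or cells["condition"].nunique() < 2:
        result.ok = False
        return result
    y = cells[["edited", "unedited"]].to_numpy(float)
    x_full, x_red = _design_matrices(cells, contrast)
    try:
        fit_full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit(
            maxiter=_MAXITER, tol=_TOL)
        fit_red = sm.GLM(y, x_red, family=sm.families.Binomial()).fit(
            maxiter=_MAXITER, tol=_TOL)
    except Exception as exc:  # separation / numerical failure
        logger.warning("GLM failed for gene %s (%s): %s",
                       profile.gene_id, contrast, exc)
        result.ok = False
        return result
    if not (fit_full.converged and fit_red.converged) \
            or np.any(np.abs(fit_full.params) > _SEPARATION_BOUND):
        result.ok = False
        return result
    df = int(np.linalg.matrix_rank(x_full) - np.linalg.matrix_rank(x_red))
    stat = max(float(fit_red.deviance - fit_full.deviance), 0.0)
    result.statistic = stat
    result.df = df
    result.pvalue = float(chi2.sf(stat, df)) if df > 0 else 1.0
    # per-position mean frequency shift (stress - control)
    freq = cells.assign(
        f=cells["edited"] / (cells["edited"] + cells["unedited"]))
    means = freq.groupby(["position", "condition"])["f"].mean().unstack()
    if stress in means and control in means:
        shift = (means[stress] - means[control]).dropna()
        result.mean_shift = {int(p): float(v) for p, v in shift.items()}
    return result


def differential_editing(profiles: dict[str, GeneEditProfile],
                         contrasts: list[tuple[str, str]],
                         alpha: float = 0.05, min_positions: int = 2,
                         min_coverage: int = 1,
                         replicates: dict[str, list] | None = None):
    """Run the per-gene GLM for every contrast with BH correction.

    Returns (results, summary): results maps contrast -> list of
    DifferentialEditingResult (tested genes only); summary reports
    per-contrast significant counts, the union over contrasts, and the
    multi-stressor overlap."""
    results: dict[tuple[str, str], list[DifferentialEditingResult]] = {}
    sig_genes: dict[tuple[str, str], set] = {}
    for contrast in contrasts:
        testable = filter_testable_genes(
            profiles, contrast, min_positions, min_coverage, replicates)
        fits = [fit_differential_glm(prof, contrast)
                for _, prof in sorted(testable.items())]
        ok = [r for r in fits if r.ok]
        if ok:
            qvals = bh_adjust([r.pvalue for r in ok])
            for r, q in zip(ok, qvals):
                r.qvalue = float(q)
        results[contrast] = fits
        sig_genes[contrast] = {r.gene_id for r in ok if r.qvalue < alpha}
    union = set().union(*sig_genes.values()) if sig_genes else set()
    multi = {g for g in union
             if sum(g in s for s in sig_genes.values()) >= 2}
    summary = {
        "per_contrast": {f"{s}_vs_{c}": len(sig_genes[(s, c)])
                         for (s, c) in contrasts},
        "union": len(union),
        "multi_stressor": len(multi),
        "union_genes": sorted(union),
    }
    return results, summary


def results_to_dataframe(fits: list[DifferentialEditingResult]):
    rows = []
    for r in fits:
        rows.append({
            "gene_id": r.gene_id, "stress": r.contrast[0],
            "control": r.contrast[1], "statistic": r.statistic,
            "df": r.df, "pvalue": r.pvalue, "qvalue": r.qvalue,
            "n_positions": r.n_positions, "ok": r.ok,
            "mean_shift": ";".join(f"{p + 1}:{v:.4f}"
                                   for p, v in sorted(r.mean_shift.items())),
        })
    return pd.DataFrame(rows)
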