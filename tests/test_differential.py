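import numpy as np
import pandas as pd
import pytest

from conftest import make_count_table, make_site
from editome.differential import (GeneEditProfile, build_gene_profiles,
                                  differential_editing,
                                  filter_testable_genes,
                                  fit_differential_glm)
from editome.reference import GeneIndex, GeneModel

CONTRAST = ("stress", "control")


def profile_from_arrays(gene_id, positions, conditions, reps, edited,
                        coverage):
    """edited/coverage: dicts keyed (condition, rep, position)."""
    rows = []
    for c in conditions:
        for r in reps:
            for p in positions:
                key = (c, r, p)
                if key not in coverage:
                    continue
                n = coverage[key]
                e = edited[key]
                rows.append({"condition": c, "replicate": r, "position": p,
                             "edited": e, "unedited": n - e})
    return GeneEditProfile(gene_id, list(positions), pd.DataFrame(rows))


def simulate_profile(gene_id, rng, f_control, f_stress, positions=(10, 20),
                     reps=4, coverage=50):
    edited, cov = {}, {}
    for c, f in (("control", f_control), ("stress", f_stress)):
        for r in range(reps):
            for p in positions:
                cov[(c, r, p)] = coverage
                edited[(c, r, p)] = int(rng.binomial(coverage, f))
    return profile_from_arrays(gene_id, positions, ("control", "stress"),
                               range(reps), edited, cov)


class TestBuildProfiles:
    def _setup(self):
        g = GeneModel("g1", "c1", "+", 0, 100, exons=[(0, 100)])
        index = GeneIndex([g])
        sites = [make_site(position=p, ref="C", alts=("T",)) for p in
                 (10, 20, 30)]
        tables = {}
        for cond in ("control", "stress"):
            for rep in ("r1", "r2", "r3", "r4"):
                rows = [("c1", p, "C", {"C": 40, "T": 10}) for p in
                        (10, 20, 30)]
                tables[(cond, rep)] = make_count_table(rows)
        return index, sites, tables

    def test_profile_shape(self):
        index, sites, tables = self._setup()
        profiles = build_gene_profiles(sites, tables, index)
        assert set(profiles) == {"g1"}
        assert profiles["g1"].n_cells() == 3 * 8  # 3 edits x 8 samples

    def test_missing_cell_for_uncovered_replicate(self):
        index, sites, tables = self._setup()
        rows = [("c1", 10, "C", {"C": 40, "T": 10}),
                ("c1", 20, "C", {"C": 40, "T": 10})]  # position 30 absent
        tables[("stress", "r4")] = make_count_table(rows)
        profiles = build_gene_profiles(sites, tables, index)
        assert profiles["g1"].n_cells() == 23

    def test_intergenic_edits_have_no_profile(self):
        index, _, tables = self._setup()
        sites = [make_site(position=500)]
        assert build_gene_profiles(sites, tables, index) == {}


class TestTestableFilter:
    def test_fully_covered_gene_kept(self):
        rng = np.random.default_rng(0)
        prof = simulate_profile("g1", rng, 0.3, 0.3)
        kept = filter_testable_genes({"g1": prof}, CONTRAST)
        assert "g1" in kept

    def test_one_uncovered_replicate_drops_gene(self):
        rng = np.random.default_rng(0)
        prof = simulate_profile("g1", rng, 0.3, 0.3)
        cells = prof.cells
        prof.cells = cells[~((cells.condition == "stress")
                             & (cells.replicate == 2)
                             & (cells.position == 20))]
        kept = filter_testable_genes({"g1": prof}, CONTRAST)
        assert kept == {}

    def test_single_position_gene_dropped(self):
        rng = np.random.default_rng(0)
        prof = simulate_profile("g1", rng, 0.3, 0.3, positions=(10,))
        assert filter_testable_genes({"g1": prof}, CONTRAST) == {}

    def test_explicit_replicate_roster(self):
        rng = np.random.default_rng(0)
        prof = simulate_profile("g1", rng, 0.3, 0.3, reps=3)
        roster = {"control": [0, 1, 2, 3], "stress": [0, 1, 2, 3]}
        assert filter_testable_genes({"g1": prof}, CONTRAST,
                                     replicates=roster) == {}


class TestFitGlm:
    def test_identical_counts_give_null_result(self):
        edited, cov = {}, {}
        for c in ("control", "stress"):
            for r in range(4):
                for p in (10, 20):
                    cov[(c, r, p)] = 50
                    edited[(c, r, p)] = 15
        prof = profile_from_arrays("g1", (10, 20), ("control", "stress"),
                                   range(4), edited, cov)
        res = fit_differential_glm(prof, CONTRAST)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.pvalue == pytest.approx(1.0)

    def test_statistic_nonnegative_p_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            prof = simulate_profile("g", rng, 0.3, 0.3)
            res = fit_differential_glm(prof, CONTRAST)
            assert res.statistic >= 0
            assert 0 < res.pvalue <= 1

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        prof = simulate_profile("g1", rng, 0.2, 0.8)
        res = fit_differential_glm(prof, CONTRAST)
        assert res.pvalue < 1e-10
        assert res.df == 2  # condition + condition x position (2 positions)
        for shift in res.mean_shift.values():
            assert shift == pytest.approx(0.6, abs=0.15)

    def test_position_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        prof = simulate_profile("g1", rng, 0.25, 0.45,
                                positions=(10, 20, 30))
        res1 = fit_differential_glm(prof, CONTRAST)
        relabelled = prof.cells.copy()
        relabelled["position"] = relabelled["position"].map(
            {10: 99, 20: 7, 30: 55})
        prof2 = GeneEditProfile("g1", [7, 55, 99], relabelled)
        res2 = fit_differential_glm(prof2, CONTRAST)
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-9)

    def test_scaling_counts_changes_statistic(self):
        """x10 counts = more information; pooling guard by construction."""
        rng = np.random.default_rng(2)
        prof = simulate_profile("g1", rng, 0.25, 0.35)
        res1 = fit_differential_glm(prof, CONTRAST)
        scaled = prof.cells.copy()
        scaled[["edited", "unedited"]] *= 10
        res2 = fit_differential_glm(
            GeneEditProfile("g1", prof.positions, scaled), CONTRAST)
        assert res2.statistic > res1.statistic

    def test_type_one_error_calibration_small(self):
        rng = np.random.default_rng(33)
        pvals = []
        for i in range(300):
            prof = simulate_profile(f"g{i}", rng, 0.3, 0.3)
            res = fit_differential_glm(prof, CONTRAST)
            if res.ok:
                pvals.append(res.pvalue)
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= frac <= 0.09

    def test_condition_logodds_recovery(self):
        """Mean estimated condition log-odds shift within +-0.2 of truth
        at coverage 100, 4+4 replicates."""
        rng = np.random.default_rng(10)
        truth = np.log(0.8 / 0.2) - np.log(0.2 / 0.8)
        shifts = []
        for i in range(20):
            prof = simulate_profile(f"g{i}", rng, 0.2, 0.8, coverage=100)
            res = fit_differential_glm(prof, CONTRAST)
            # frequency-scale shift back-transformed per position
            for p, s in res.mean_shift.items():
                cells = prof.cells
                ctrl = cells[(cells.condition == "control")
                             & (cells.position == p)]
                f0 = ctrl.edited.sum() / (ctrl.edited + ctrl.unedited).sum()
                f1 = f0 + s
                shifts.append(np.log(f1 / (1 - f1)) - np.log(f0 / (1 - f0)))
        assert np.mean(shifts) == pytest.approx(truth, abs=0.2)


class TestDifferentialEditing:
    def test_recovery_simulation(self):
        rng = np.random.default_rng(4)
        profiles = {}
        for i in range(90):
            profiles[f"null{i}"] = simulate_profile(f"null{i}", rng, 0.3, 0.3)
        for i in range(10):
            profiles[f"shift{i}"] = simulate_profile(f"shift{i}", rng,
                                                     0.2, 0.8)
        results, summary = differential_editing(profiles, [CONTRAST])
        sig = {r.gene_id for r in results[CONTRAST] if r.significant}
        assert len([g for g in sig if g.startswith("shift")]) >= 9
        assert len([g for g in sig if g.startswith("null")]) <= 2

    def test_union_and_overlap_semantics(self):
        rng = np.random.default_rng(6)
        edited, cov = {}, {}
        for c in ("control", "heat", "cold"):
            f = 0.2 if c == "control" else 0.8
            for r in range(4):
                for p in (10, 20):
                    cov[(c, r, p)] = 80
                    edited[(c, r, p)] = int(rng.binomial(80, f))
        prof = profile_from_arrays("g1", (10, 20),
                                   ("control", "heat", "cold"), range(4),
                                   edited, cov)
        results, summary = differential_editing(
            {"g1": prof}, [("heat", "control"), ("cold", "control")])
        assert summary["union"] == 1  # counted once in the union
        assert summary["per_contrast"] == {"heat_vs_control": 1,
                                           "cold_vs_control": 1}
        assert summary["multi_stressor"] == 1

    def test_empty_profiles(self):
        results, summary = differential_editing({}, [CONTRAST])
        assert results[CONTRAST] == []
        assert summary["union"] == 0
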