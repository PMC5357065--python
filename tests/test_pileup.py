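import numpy as np
import pysam
import pytest

from conftest import make_count_table
from editome.pileup import (SiteCountTable, deduplicate_alignments,
                            mask_homopolymers, pileup_from_sam,
                            read_count_table)
from editome.reference import GenomeReference
from editome.simulate import random_reads, sam_text


class TestHomopolymerMask:
    def test_no_runs(self):
        g = GenomeReference({"c1": "ACGTACGT"})
        assert len(mask_homopolymers(g, 4)) == 0

    def test_run_of_four_masked(self):
        g = GenomeReference({"c1": "AAAAC"})
        m = mask_homopolymers(g, 4)
        assert m.positions == frozenset({("c1", p) for p in range(4)})

    def test_run_of_three_boundary(self):
        g = GenomeReference({"c1": "AAAC"})
        assert len(mask_homopolymers(g, 4)) == 0

    def test_n_never_forms_run(self):
        g = GenomeReference({"c1": "NNNNN"})
        assert len(mask_homopolymers(g, 4)) == 0

    def test_run_at_contig_end(self):
        g = GenomeReference({"c1": "CGTTTT"})
        m = mask_homopolymers(g, 4)
        assert m.positions == frozenset({("c1", p) for p in range(2, 6)})

    def test_min_run_validation(self):
        with pytest.raises(ValueError):
            mask_homopolymers(GenomeReference({"c1": "ACGT"}), 1)


def _genome(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return GenomeReference(
        {"c1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])})


def _write_sam(tmp_path, reads, genome, name="a.sam"):
    p = tmp_path / name
    p.write_text(sam_text(reads, genome))
    return p


def _parse(tmp_path, reads, genome):
    path = _write_sam(tmp_path, reads, genome)
    with pysam.AlignmentFile(str(path), "r") as fh:
        return list(fh)


class TestDeduplicate:
    def test_identical_pairs_collapse(self, tmp_path):
        genome = _genome()
        r = {"qname": "a", "contig": "c1", "pos": 10,
             "seq": genome.slice("c1", 10, 60), "paired": True,
             "mate_pos": 100}
        reads = _parse(tmp_path, [r, {**r, "qname": "b"}], genome)
        assert len(deduplicate_alignments(reads)) == 1

    def test_distinct_keys_unchanged(self, tmp_path):
        genome = _genome()
        reads = _parse(tmp_path, [
            {"qname": "a", "contig": "c1", "pos": 10,
             "seq": genome.slice("c1", 10, 60)},
            {"qname": "b", "contig": "c1", "pos": 11,
             "seq": genome.slice("c1", 11, 61)},
        ], genome)
        assert len(deduplicate_alignments(reads)) == 2

    def test_three_duplicates_plus_unique(self, tmp_path):
        genome = _genome()
        dup = {"contig": "c1", "pos": 5, "seq": genome.slice("c1", 5, 55)}
        reads = _parse(tmp_path, [
            {**dup, "qname": f"d{i}"} for i in range(3)
        ] + [{"qname": "u", "contig": "c1", "pos": 50,
              "seq": genome.slice("c1", 50, 100)}], genome)
        assert len(deduplicate_alignments(reads)) == 2

    def test_strand_distinguishes(self, tmp_path):
        genome = _genome()
        base = {"contig": "c1", "pos": 10, "seq": genome.slice("c1", 10, 60)}
        reads = _parse(tmp_path, [
            {**base, "qname": "f"}, {**base, "qname": "r", "reverse": True},
        ], genome)
        assert len(deduplicate_alignments(reads)) == 2


class TestPileupFromSam:
    def test_end_trim_nine(self, tmp_path):
        genome = _genome()
        reads = [{"qname": "r", "contig": "c1", "pos": 20,
                  "seq": genome.slice("c1", 20, 70)}]
        t = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome)
        assert len(t) == 50 - 2 * 9
        assert set(t.pos) == set(range(29, 61))
        assert (t.n == 1).all()

    def test_trim_zero(self, tmp_path):
        genome = _genome()
        reads = [{"qname": "r", "contig": "c1", "pos": 20,
                  "seq": genome.slice("c1", 20, 70)}]
        t = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome,
                            end_trim=0)
        assert len(t) == 50

    def test_mapq0_excluded(self, tmp_path):
        genome = _genome()
        reads = [{"qname": "r", "contig": "c1", "pos": 20, "mapq": 0,
                  "seq": genome.slice("c1", 20, 70)}]
        t = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome)
        assert len(t) == 0

    def test_multihit_tag_excluded(self, tmp_path):
        genome = _genome()
        reads = [{"qname": "r", "contig": "c1", "pos": 20, "nh": 2,
                  "seq": genome.slice("c1", 20, 70)}]
        t = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome)
        assert len(t) == 0
        t2 = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome,
                             unique_only=False)
        assert len(t2) == 32

    def test_masked_positions_absent(self, tmp_path):
        genome = GenomeReference({"c1": "ACGT" * 10 + "AAAA" + "ACGT" * 10})
        mask = mask_homopolymers(genome, 4)
        reads = [{"qname": "r", "contig": "c1", "pos": 20,
                  "seq": genome.slice("c1", 20, 70)}]
        t = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome,
                            mask=mask, end_trim=0)
        assert not any(40 <= p < 44 for p in t.pos)

    def test_strand_recorded(self, tmp_path):
        genome = _genome()
        reads = [{"qname": "f", "contig": "c1", "pos": 20,
                  "seq": genome.slice("c1", 20, 70)},
                 {"qname": "r", "contig": "c1", "pos": 21, "reverse": True,
                  "seq": genome.slice("c1", 21, 71)}]
        t = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome,
                            end_trim=0)
        i = t.row("c1", 30)
        assert t.counts[i, :, 0].sum() == 1  # forward
        assert t.counts[i, :, 1].sum() == 1  # reverse

    def test_trim_equivalence_with_pretrimmed_reads(self, tmp_path):
        """end_trim=9 on full reads == end_trim=0 on reads whose first and
        last 9 cycles were clipped off."""
        genome = _genome(500, seed=3)
        rng = np.random.default_rng(42)
        reads = random_reads(genome, 60, 50, rng, error_rate=0.05)
        clipped = [{**r, "pos": r["pos"] + 9, "seq": r["seq"][9:-9]}
                   for r in reads]
        t_full = pileup_from_sam(_write_sam(tmp_path, reads, genome, "f.sam"),
                                 genome, end_trim=9, dedup=False)
        t_clip = pileup_from_sam(_write_sam(tmp_path, clipped, genome,
                                            "c.sam"), genome, end_trim=0,
                                 dedup=False)
        assert np.array_equal(t_full.pos, t_clip.pos)
        assert np.array_equal(t_full.counts, t_clip.counts)

    def test_roundtrip_against_independent_count(self, tmp_path):
        """pileup_from_sam reproduces a plain per-read tally."""
        genome = _genome(300, seed=9)
        rng = np.random.default_rng(7)
        reads = random_reads(genome, 40, 50, rng, error_rate=0.02)
        expected: dict = {}
        for r in reads:
            for off in range(9, 41):  # [end_trim, len - end_trim)
                pos = r["pos"] + off
                base = r["seq"][off]
                strand = 1 if r["reverse"] else 0
                key = (pos, base, strand)
                expected[key] = expected.get(key, 0) + 1
        t = pileup_from_sam(_write_sam(tmp_path, reads, genome), genome,
                            dedup=False)
        from editome.pileup import BASE_INDEX
        total = 0
        for (pos, base, strand), cnt in expected.items():
            i = t.row("c1", pos)
            assert t.counts[i, BASE_INDEX[base], strand] == cnt
            total += cnt
        assert t.counts.sum() == total


class TestCountTableIO:
    def test_read_with_strand_columns(self, tmp_path):
        genome = GenomeReference({"c1": "ACGTACGTACGTC"})
        t = make_count_table([("c1", 9, "C", {"C": (30, 35), "T": (2, 2)})])
        p = tmp_path / "t.tsv"
        t.to_tsv(p)
        back = read_count_table(p, genome)
        i = back.row("c1", 9)
        assert back.n[i] == 69
        assert back.base_counts[i, 3] == 4  # T
        assert back.has_strand

    def test_read_without_strand_columns(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("contig\tposition\tref\tA\tC\tG\tT\nc1\t10\tC\t0\t65\t0\t4\n")
        t = read_count_table(p)
        assert not t.has_strand
        assert t.n[0] == 69

    def test_empty_table(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("contig\tposition\tref\tA\tC\tG\tT\n")
        assert len(read_count_table(p)) == 0

    def test_ref_mismatch_rejected(self, tmp_path):
        genome = GenomeReference({"c1": "ACGTACGTACGTC"})
        p = tmp_path / "t.tsv"
        p.write_text("contig\tposition\tref\tA\tC\tG\tT\nc1\t10\tT\t0\t65\t0\t4\n")
        with pytest.raises(ValueError, match="disagrees"):
            read_count_table(p, genome)

    def test_roundtrip(self, tmp_path):
        t = make_count_table([("c1", 4, "A", {"A": (10, 12), "G": (1, 0)}),
                              ("c1", 7, "G", {"G": (5, 5)})])
        p = tmp_path / "t.tsv"
        t.to_tsv(p)
        back = read_count_table(p)
        assert np.array_equal(back.counts, t.counts)
        assert np.array_equal(back.pos, t.pos)


class TestMerge:
    def test_merge_sums_positionwise(self):
        t1 = make_count_table([("c1", 4, "A", {"A": 10, "G": 1}),
                               ("c1", 7, "G", {"G": 5})])
        t2 = make_count_table([("c1", 4, "A", {"A": 3, "T": 2})])
        merged = SiteCountTable.merge([t1, t2])
        i = merged.row("c1", 4)
        assert merged.n[i] == 16
        assert merged.base_counts[i, 0] == 13  # A
        assert merged.n[merged.row("c1", 7)] == 5

    def test_merge_random_split_oracle(self):
        rng = np.random.default_rng(12)
        rows = [("c1", int(p), "A", {"A": int(rng.integers(0, 50)),
                                     "G": int(rng.integers(0, 5))})
                for p in range(30)]
        full = make_count_table(rows)
        t1 = make_count_table(rows[:17])
        t2 = make_count_table(rows[17:])
        merged = SiteCountTable.merge([t1, t2])
        assert np.array_equal(merged.counts, full.counts)

    def test_merge_inconsistent_ref_rejected(self):
        t1 = make_count_table([("c1", 4, "A", {"A": 1})])
        t2 = make_count_table([("c1", 4, "C", {"C": 1})])
        with pytest.raises(ValueError, match="inconsistent"):
            SiteCountTable.merge([t1, t2])
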