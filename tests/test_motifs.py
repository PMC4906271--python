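"""Motif scanning, background sampling, k-mer ranking and arrays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistarget_compare import (
    GeneModel,
    GenomicInterval,
    MotifModel,
    SequenceRecord,
    anchor_array,
    builtin_library,
    compare_arrays,
    fold_enrichment,
    kmer_enrichment,
    sample_noncoding,
    scan,
)
from cistarget_compare.io import revcomp

from .conftest import random_dna
from .oracles import scan_oracle

ADF1 = "TGGCTGCCGTCGCGAT"
MAD1 = "GCCGTCGC"


class TestScanConsensus:
    def test_mad1_within_adf1_site(self):
        hits = scan(MotifModel("MAD1", "MAD1", iupac=MAD1), ADF1, both_strands=False)
        assert [(h.position, h.strand) for h in hits] == [(5, "+")]

    def test_taat_both_strands(self):
        hits = scan(MotifModel("c", "Ubx", iupac="TAAT"), "ATAATTAAT", both_strands=True)
        assert [(h.position, h.strand) for h in hits] == [(1, "+"), (3, "-"), (5, "+")]

    def test_motif_longer_than_sequence(self):
        assert scan(MotifModel("m", "t", iupac="A" * 20), "ACGTACGTAC") == []

    def test_degenerate_codes(self):
        hits = scan(MotifModel("u", "Ubx", iupac="ATAATS"), "ATAATGATAATC", both_strands=False)
        assert [h.position for h in hits] == [0, 6]

    def test_sequence_n_never_matches(self):
        assert scan(MotifModel("m", "t", iupac="TAAT"), "TANT", both_strands=False) == []
        # motif code N matches everything including N
        assert len(scan(MotifModel("m", "t", iupac="TANT"), "TANT", both_strands=False)) == 1

    def test_overlapping_hits_all_counted(self):
        hits = scan(MotifModel("m", "t", iupac="AAA"), "AAAAA", both_strands=False)
        assert [h.position for h in hits] == [0, 1, 2]

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(21)
        codes = list("ACGTRYSWKMBDHVN")
        for _ in range(30):
            seq = random_dna(rng, 500)
            length = int(rng.integers(4, 11))
            pattern = "".join(rng.choice(codes) for _ in range(length))
            got = [(h.position, h.strand) for h in scan(MotifModel("m", "t", iupac=pattern), seq)]
            assert sorted(got) == scan_oracle(pattern, seq, True)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=300), st.sampled_from(
        ["TAAT", "ATAATS", "GAGAG", "GCCGTCGC"]))
    def test_revcomp_symmetry(self, seq, pattern):
        """Both-strand hit counts are invariant under reverse complement."""
        motif = MotifModel("m", "t", iupac=pattern)
        assert len(scan(motif, seq)) == len(scan(motif, revcomp(seq)))


class TestScanMatrix:
    def _motif(self, threshold=None):
        # strongly peaked TAAT matrix
        m = np.full((4, 4), 0.01)
        for i, base in enumerate("TAAT"):
            m[i, "ACGT".index(base)] = 0.97
        return MotifModel("mat", "t", matrix=m, score_threshold=threshold)

    def test_recovers_consensus_site(self):
        motif = self._motif()
        hits = scan(motif, "GGTAATGG", both_strands=False)
        assert [h.position for h in hits] == [2]
        assert hits[0].score == pytest.approx(motif.max_score)

    def test_threshold_excludes_weak_sites(self):
        strict = self._motif(threshold=None)  # default 0.8 * max
        assert scan(strict, "GGTACTGG", both_strands=False) == []
        permissive = self._motif(threshold=-100.0)
        assert len(scan(permissive, "GGTACTGG", both_strands=False)) > 0

    def test_reverse_strand_position_forward_coords(self):
        hits = scan(self._motif(), "GGATTAGG")  # ATTA = revcomp(TAAT)
        assert [(h.position, h.strand) for h in hits] == [(2, "-")]

    def test_window_with_n_never_matches(self):
        assert scan(self._motif(), "GGTANTGG", both_strands=False) == []


class TestSampleNoncoding:
    def _genome(self, rng, n_scaffolds=2, length=5000):
        return [SequenceRecord(f"s{i}", random_dna(rng, length)) for i in range(n_scaffolds)]

    def test_gene_free_genome_all_draws_succeed(self):
        rng = np.random.default_rng(0)
        genome = self._genome(rng)
        draws = sample_noncoding(genome, [], 10, [100] * 10, seed=1)
        assert len(draws) == 10
        assert all(len(d) == 100 for d in draws)

    def test_fully_covered_genome_errors(self):
        rng = np.random.default_rng(0)
        genome = self._genome(rng)
        genes = [GeneModel(f"g{i}", GenomicInterval(rec.id, 0, len(rec.residues)))
                 for i, rec in enumerate(genome)]
        with pytest.raises(ValueError, match="insufficient"):
            sample_noncoding(genome, genes, 5, [100] * 5, seed=1)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        genome = self._genome(rng)
        a = sample_noncoding(genome, [], 20, [50] * 20, seed=7)
        b = sample_noncoding(genome, [], 20, [50] * 20, seed=7)
        assert a == b

    def test_draws_never_intersect_gene_bodies(self):
        rng = np.random.default_rng(5)
        genome = self._genome(rng, n_scaffolds=1, length=20_000)
        genes = [GeneModel(f"g{i}", GenomicInterval("s0", s, s + 500))
                 for i, s in enumerate(range(1000, 19_000, 2000))]
        gene_seqs = {genome[0].residues[g.interval.start:g.interval.end] for g in genes}
        draws = sample_noncoding(genome, genes, 50, [200] * 50, seed=3)
        # verify by locating each draw in the scaffold and checking overlap
        seq = genome[0].residues
        for d in draws:
            pos = seq.find(d)
            assert pos >= 0
            for g in genes:
                assert pos + len(d) <= g.interval.start or pos >= g.interval.end


class TestFoldEnrichment:
    def test_absent_motif_zero_fold(self):
        rng = np.random.default_rng(8)
        genome = [SequenceRecord("s", random_dna(rng, 30_000))]
        fg = sample_noncoding(genome, [], 10, [200] * 10, seed=2)
        motif = MotifModel("x", "t", iupac="ACGTACGTACGTACGT")  # effectively absent
        fe = fold_enrichment(fg, motif, genome, [], n_draws=20, seed=3)
        assert fe.fg_density == 0.0
        assert fe.fold == 0.0
        assert fe.empirical_p > 0.9

    def test_null_fold_near_one(self):
        rng = np.random.default_rng(9)
        genome = [SequenceRecord("s", random_dna(rng, 60_000))]
        fg = sample_noncoding(genome, [], 40, [500] * 40, seed=4)
        fe = fold_enrichment(fg, MotifModel("t", "Ubx", iupac="TAAT"), genome, [],
                             n_draws=30, seed=5)
        assert 0.7 <= fe.fold <= 1.35
        assert fe.n_background_draws == 30

    def test_empirical_p_never_zero(self):
        rng = np.random.default_rng(10)
        genome = [SequenceRecord("s", random_dna(rng, 20_000))]
        fg = ["TAAT" * 50]  # saturated foreground
        fe = fold_enrichment(fg, MotifModel("t", "Ubx", iupac="TAAT"), genome, [],
                             n_draws=20, seed=6)
        assert fe.empirical_p == pytest.approx(1 / 21)
        assert fe.fold > 5

    def test_requires_minimum_draws(self):
        genome = [SequenceRecord("s", "ACGT" * 100)]
        with pytest.raises(ValueError):
            fold_enrichment(["ACGT"], MotifModel("t", "t", iupac="TAAT"),
                            genome, [], n_draws=5)


class TestKmerEnrichment:
    def test_planted_hexamer_ranks_first(self):
        rng = np.random.default_rng(12)
        bg = [random_dna(rng, 2000) for _ in range(10)]
        planted = "TAATGG"
        fg = []
        for _ in range(10):
            seq = list(random_dna(rng, 2000))
            for pos in rng.integers(0, 1990, size=30):
                seq[pos:pos + 6] = planted
            fg.append("".join(seq))
        top = kmer_enrichment(fg, bg, k=6, top_n=1)[0]
        canonical = min(planted, revcomp(planted))
        assert top[0] == canonical

    def test_null_folds_bounded(self):
        rng = np.random.default_rng(13)
        fg = [random_dna(rng, 30_000)]
        bg = [random_dna(rng, 30_000)]
        rows = kmer_enrichment(fg, bg, k=4)
        folds = [r[3] for r in rows]
        assert all(0.5 <= f <= 2.0 for f in folds)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGTACGT"], ["ACGTACGT"], k=13)
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGTACGT"], ["ACGTACGT"], k=3)

    def test_k_longer_than_shortest_sequence(self):
        with pytest.raises(ValueError, match="shortest"):
            kmer_enrichment(["ACGTA"], ["ACGTACGTACGT"], k=6)

    def test_canonicalisation_merges_strands(self):
        rows = kmer_enrichment(["AAAATTTT"], ["AAAATTTT"], k=4)
        kmers = [r[0] for r in rows]
        assert "AAAA" in kmers and "TTTT" not in kmers  # TTTT counted as AAAA


class TestAnchorArray:
    def test_planted_sites_at_signed_offsets(self):
        rng = np.random.default_rng(14)
        library = [MotifModel("GAF", "GAF", iupac="GAGAGAG"),
                   MotifModel("MAD1", "MAD1", iupac=MAD1)]
        seq = list("C" * 200)
        anchor = 100
        seq[anchor - 30:anchor - 30 + 7] = "GAGAGAG"
        seq[anchor + 12:anchor + 12 + 8] = MAD1
        arr = anchor_array("".join(seq), anchor, library, window_bp=50)
        tf_offsets = [(tf, off) for tf, off, strand in arr.hits]
        assert ("GAF", -30) in tf_offsets
        assert ("MAD1", 12) in tf_offsets
        offsets = [off for _, off, _ in arr.hits]
        assert offsets == sorted(offsets)

    def test_adf1_site_implies_mad1_site_offset_five(self):
        library = [MotifModel("Adf1", "Adf-1", iupac=ADF1),
                   MotifModel("MAD1", "MAD1", iupac=MAD1)]
        seq = "C" * 90 + ADF1 + "C" * 94
        arr = anchor_array(seq, 100, library, window_bp=100)
        by_tf = {tf: off for tf, off, _ in arr.hits}
        assert by_tf["MAD1"] == by_tf["Adf-1"] + 5

    def test_window_zero_only_anchor_start(self):
        library = [MotifModel("m", "t", iupac="TAAT")]
        seq = "TAAT" + "C" * 50 + "TAAT" + "C" * 50
        arr = anchor_array(seq, 54, library, window_bp=0)
        assert [(tf, off) for tf, off, _ in arr.hits] == [("t", 0)]

    def test_anchor_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            anchor_array("ACGT", 10, [], 5)


class TestCompareArrays:
    def test_adf1_absence_pattern(self):
        from cistarget_compare import BindingSiteArray

        a = BindingSiteArray(0, 100, (("Adf-1", -3, "+"), ("GAF", -30, "+"), ("MAD1", 2, "+")))
        b = BindingSiteArray(0, 100, (("GAF", -28, "+"), ("MAD1", 5, "+")))
        comp = compare_arrays(a, b)
        assert comp.a_only_tfs == {"Adf-1"}
        assert comp.shared_tfs == {"GAF", "MAD1"}
        assert comp.b_only_tfs == set()
        assert comp.per_tf_offset_pairs["MAD1"] == ((2, 5),)

    def test_identical_arrays(self):
        from cistarget_compare import BindingSiteArray

        a = BindingSiteArray(0, 100, (("GAF", 1, "+"),))
        comp = compare_arrays(a, a)
        assert comp.a_only_tfs == comp.b_only_tfs == set()

    def test_disjoint_tf_sets(self):
        from cistarget_compare import BindingSiteArray

        a = BindingSiteArray(0, 100, (("GAF", 1, "+"),))
        b = BindingSiteArray(0, 100, (("MAD1", 1, "+"),))
        comp = compare_arrays(a, b)
        assert comp.shared_tfs == set()
        assert comp.a_only_tfs == {"GAF"} and comp.b_only_tfs == {"MAD1"}


def test_builtin_library_contains_documented_motifs():
    by_id = {m.motif_id: m for m in builtin_library()}
    assert by_id["UbxCore"].iupac == "TAAT"
    assert by_id["Ubx"].iupac == "ATAATS"
    assert by_id["Adf1"].iupac == ADF1
    assert by_id["MAD1"].iupac == MAD1
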