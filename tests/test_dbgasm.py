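"""De Bruijn assembly core: counting, cleaning, contigs, filtering,
merging, polishing."""

import numpy as np
import pytest

from hapasm import dbgasm as dbg
from hapasm import simforge as sf
from hapasm._seq import canonical, random_dna, revcomp
from hapasm.simforge import ReadPair


def windows(seq, length=100, step=10):
    """Error-free tiling pseudo-reads."""
    return [seq[i : i + length] for i in range(0, len(seq) - length + 1, step)]


class TestCountKmers:
    def test_instance_count(self):
        counts = dbg.count_kmers(["ACGTACGT"], 4)
        assert sum(counts.values()) == 5

    def test_reverse_complement_collapses(self):
        a = dbg.count_kmers(["ACGTTGCACCA"], 5)
        b = dbg.count_kmers([revcomp("ACGTTGCACCA")], 5)
        assert a == b

    def test_k_longer_than_reads_gives_empty(self):
        assert dbg.count_kmers(["ACGT"], 10) == {}


class TestEstimateBestK:
    def test_matches_bruteforce_spectrum_oracle(self, rng):
        seq = random_dna(rng, 10_000)
        reads = windows(seq, 150, 5)  # ~30x
        candidates = [21, 31, 41]

        def oracle(k):  # independent exhaustive count of distinct solid kmers
            seen = {}
            for r in reads:
                for i in range(len(r) - k + 1):
                    km = canonical(r[i : i + k])
                    seen[km] = seen.get(km, 0) + 1
            return sum(1 for c in seen.values() if c >= 3)

        scores = {k: oracle(k) for k in candidates}
        best = max(candidates, key=lambda k: (scores[k], k))
        assert dbg.estimate_best_k(reads, candidates) == best

    def test_ties_prefer_larger_k(self):
        seq = "ACGTGCA" * 300
        reads = windows(seq, 120, 1)
        k = dbg.estimate_best_k(reads, [15, 17])
        assert k == 17  # periodic sequence: same tiny spectrum at both k

    def test_candidates_longer_than_reads_raise(self):
        with pytest.raises(ValueError):
            dbg.estimate_best_k(["ACGTACGTACG"], [15, 17])

    def test_no_reads_raise(self):
        with pytest.raises(ValueError):
            dbg.estimate_best_k([], [21])

    def test_default_assembly_k_is_51(self):
        assert dbg.AssemblyParams().k == 51


class TestBuildAndClean:
    def test_error_free_reads_give_single_path(self, rng):
        seq = random_dna(rng, 3_000)
        params = dbg.AssemblyParams(k=31, min_kmer_cov=1)
        solid = dbg.solid_kmers(dbg.count_kmers(windows(seq), params.k), 1)
        g = dbg.build_and_clean(solid, params)
        contigs = dbg.extract_contigs(g, params)
        assert len(contigs) == 1
        got = contigs[0].sequence
        assert got == seq or got == revcomp(seq)

    def test_single_error_branch_removed(self, rng):
        seq = random_dna(rng, 2_000)
        reads = windows(seq)
        bad = list(reads[40])
        bad[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[50]]
        reads[40] = "".join(bad)
        params = dbg.AssemblyParams(k=31, min_kmer_cov=2)
        solid = dbg.solid_kmers(dbg.count_kmers(reads, params.k), 2)
        g = dbg.build_and_clean(solid, params)
        contigs = dbg.extract_contigs(g, params)
        assert len(contigs) == 1
        # coverage < 2 at the tiling edges loses a few terminal kmers
        got = contigs[0].sequence
        assert got in seq or got in revcomp(seq)
        assert len(got) >= len(seq) - 40

    def test_heterozygous_snv_bubble_pops_to_higher_coverage(self, rng):
        seq = random_dna(rng, 1_000)
        alt = seq[:500] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[500]] + seq[501:]
        reads = windows(seq, 100, 5) * 3 + windows(alt, 100, 5)  # 3:1 coverage
        params = dbg.AssemblyParams(k=31, min_kmer_cov=2)
        solid = dbg.solid_kmers(dbg.count_kmers(reads, params.k), 2)
        contigs = dbg.extract_contigs(dbg.build_and_clean(solid, params), params)
        assert len(contigs) == 1
        assert contigs[0].sequence in (seq, revcomp(seq))

    def test_empty_spectrum_raises(self):
        with pytest.raises(dbg.EmptyGraphError):
            dbg.build_and_clean({}, dbg.AssemblyParams())

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            dbg.AssemblyParams(k=50)
        with pytest.raises(ValueError):
            dbg.AssemblyParams(k=13)


class TestExtractContigs:
    def test_branch_point_breaks_contigs(self, rng):
        # two sequences sharing an exact internal repeat longer than k
        core = random_dna(rng, 80)
        s1 = random_dna(rng, 400) + core + random_dna(rng, 400)
        s2 = random_dna(rng, 400) + core + random_dna(rng, 400)
        params = dbg.AssemblyParams(k=31, min_kmer_cov=2, min_contig_len=62)
        reads = windows(s1, 100, 5) + windows(s2, 100, 5)
        solid = dbg.solid_kmers(dbg.count_kmers(reads, params.k), 2)
        contigs = dbg.extract_contigs(dbg.build_and_clean(solid, params), params)
        # no contig may span from s1's left flank into s2's right flank
        for c in contigs:
            for s in (c.sequence, revcomp(c.sequence)):
                assert not (s1[:200] in s and s2[-200:] in s)
                assert not (s2[:200] in s and s1[-200:] in s)

    def test_deterministic_order(self, rng):
        seq = random_dna(rng, 2_000)
        params = dbg.AssemblyParams(k=31, min_kmer_cov=2)
        solid = dbg.solid_kmers(dbg.count_kmers(windows(seq), params.k), 2)
        a = dbg.extract_contigs(dbg.build_and_clean(dict(solid), params), params)
        b = dbg.extract_contigs(dbg.build_and_clean(dict(solid), params), params)
        assert [c.sequence for c in a] == [c.sequence for c in b]
        lengths = [len(c.sequence) for c in a]
        assert lengths == sorted(lengths, reverse=True)


class TestFilterCrossContigs:
    def test_alt_guide_substring_removed(self, plain_guide):
        c = dbg.Contig("c0", plain_guide.sequence[3000:4000], 10.0, "UNMAPPED")
        kept = dbg.filter_cross_contigs([c], alt_guide=plain_guide)
        assert kept == []

    def test_random_contig_retained(self, plain_guide, rng):
        c = dbg.Contig("c0", random_dna(rng, 800), 10.0, "UNMAPPED")
        kept = dbg.filter_cross_contigs([c], alt_guide=plain_guide)
        assert kept == [c]

    def test_forty_percent_alignment_retained(self, plain_guide, rng):
        seq = plain_guide.sequence[2000:2400] + random_dna(rng, 600)
        c = dbg.Contig("c0", seq, 10.0, "UNMAPPED")
        kept = dbg.filter_cross_contigs([c], alt_guide=plain_guide)
        assert kept == [c]

    def test_no_targets_passes_everything(self, rng):
        c = dbg.Contig("c0", random_dna(rng, 500), 1.0, "UNMAPPED")
        assert dbg.filter_cross_contigs([c]) == [c]


class TestMergeContigs:
    def test_sixty_bp_end_overlap_merges(self, rng):
        whole = random_dna(rng, 1_000)
        a = dbg.Contig("a", whole[:530], 10.0, "MAPPED:0-500")
        b = dbg.Contig("b", whole[470:], 10.0, "MAPPED:400-1000")
        out = dbg.merge_contigs([a, b])
        assert len(out) == 1
        assert len(out[0].sequence) == 530 + 530 - 60
        assert out[0].sequence == whole

    def test_disjoint_contigs_unchanged(self, rng):
        a = dbg.Contig("a", random_dna(rng, 400), 1.0, "MAPPED:0-400")
        b = dbg.Contig("b", random_dna(rng, 400), 1.0, "MAPPED:500-900")
        out = dbg.merge_contigs([a, b])
        assert sorted(len(c.sequence) for c in out) == [400, 400]

    def test_containment_collapses_to_container(self, rng):
        big = random_dna(rng, 1_000)
        out = dbg.merge_contigs(
            [
                dbg.Contig("big", big, 1.0, "MAPPED:0-1000"),
                dbg.Contig("small", big[200:500], 1.0, "MAPPED:900-1200"),
            ]
        )
        assert [c.sequence for c in out] == [big]

    def test_reverse_complement_overlap_merges(self, rng):
        whole = random_dna(rng, 900)
        a = dbg.Contig("a", whole[:500], 1.0, "MAPPED:0-500")
        b = dbg.Contig("b", revcomp(whole[400:]), 1.0, "MAPPED:400-900")
        out = dbg.merge_contigs([a, b])
        assert len(out) == 1
        assert out[0].sequence in (whole, revcomp(whole))

    def test_same_bin_contigs_never_end_join(self, rng):
        whole = random_dna(rng, 1_000)
        a = dbg.Contig("a", whole[:530], 1.0, "MAPPED:0-1000")
        b = dbg.Contig("b", whole[470:], 1.0, "MAPPED:0-1000")
        out = dbg.merge_contigs([a, b])
        assert len(out) == 2

    def test_disjoint_window_bins_never_end_join(self, rng):
        # repeat-induced spurious overlap between distant windows
        whole = random_dna(rng, 600)
        a = dbg.Contig("a", whole[:400], 1.0, "MAPPED:0-400")
        b = dbg.Contig("b", whole[340:], 1.0, "MAPPED:20000-20400")
        assert len(dbg.merge_contigs([a, b])) == 2


def tile_pairs(seq, start_id=0, step=25, rl=100):
    pairs = []
    for i, s in enumerate(range(0, len(seq) - 2 * rl, step)):
        frag = seq[s : s + 2 * rl]
        pairs.append(
            ReadPair(f"p{start_id + i}", frag[:rl], "I" * rl, revcomp(frag[-rl:]), "I" * rl)
        )
    return pairs


class TestPolish:
    def test_majority_substitution_corrected(self, rng):
        seq = random_dna(rng, 600)
        wrong = seq[:300] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[300]] + seq[301:]
        contig = dbg.Contig("c", wrong, 10.0, "MERGED")
        polished, corrections = dbg.polish(contig and [contig], tile_pairs(seq))
        assert polished[0].sequence == seq
        assert any(c.kind == "SUB" and c.pos == 300 for c in corrections)

    def test_low_depth_column_never_corrected(self, rng):
        seq = random_dna(rng, 400)
        wrong = seq[:200] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[200]] + seq[201:]
        contig = dbg.Contig("c", wrong, 1.0, "MERGED")
        pairs = tile_pairs(seq)[:1]  # depth ~1-2 over the error column
        polished, corrections = dbg.polish([contig], pairs)
        assert polished[0].sequence == wrong
        assert corrections == []

    def test_error_free_reads_on_correct_contig_make_no_corrections(self, rng):
        seq = random_dna(rng, 600)
        contig = dbg.Contig("c", seq, 10.0, "MERGED")
        polished, corrections = dbg.polish([contig], tile_pairs(seq))
        assert polished[0].sequence == seq
        assert corrections == []

    def test_small_deletion_in_contig_restored(self, rng):
        seq = random_dna(rng, 600)
        wrong = seq[:300] + seq[302:]  # contig lost 2 bases
        contig = dbg.Contig("c", wrong, 10.0, "MERGED")
        polished, corrections = dbg.polish([contig], tile_pairs(seq))
        assert polished[0].sequence == seq
        assert any(c.kind == "INS" for c in corrections)
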