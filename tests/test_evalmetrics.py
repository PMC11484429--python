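"""Assembly statistics, error taxonomy, recovery scoring, PAF export."""

import math

import numpy as np
import pytest

from hapasm import evalmetrics as ev
from hapasm import simforge as sf
from hapasm._seq import random_dna, revcomp


class TestN50:
    @pytest.mark.parametrize("lengths,expected", [([100], 100), ([4, 3, 2, 1], 3)])
    def test_examples(self, lengths, expected):
        assert ev.n50(lengths) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ev.n50([])

    def test_agrees_with_bruteforce_oracle_on_1000_instances(self, rng):
        def oracle(lengths):
            total = sum(lengths)
            acc = 0
            for L in sorted(lengths, reverse=True):
                acc += L
                if acc * 2 >= total:
                    return L

        for _ in range(1000):
            lengths = [int(x) for x in rng.integers(1, 10_000, size=int(rng.integers(1, 40)))]
            assert ev.n50(lengths) == oracle(lengths)

    def test_stats_totals(self):
        st = ev.assembly_stats([10, 20, 30])
        assert (st.n_contigs, st.total_length) == (3, 60)
        assert st.n50 <= 30


class TestAlignToTruth:
    def test_identical_sequences_single_full_segment(self, rng):
        seq = random_dna(rng, 5_000)
        (seg,) = ev.align_to_truth(seq, seq)
        assert (seg.qstart, seg.qend) == (0, 5_000)
        assert (seg.tstart, seg.tend) == (0, 5_000)
        assert seg.strand == "+" and seg.events == []

    def test_truth_deletion_reported_with_exact_length(self, rng):
        truth = random_dna(rng, 6_000)
        assembly = truth[:3_000] + truth[3_500:]  # assembly misses 500 bp
        (seg,) = ev.align_to_truth(assembly, truth)
        dels = [e for e in seg.events if e.kind == "DEL"]
        assert len(dels) == 1 and dels[0].length == 500
        assert abs(dels[0].tpos - 3_000) <= 5

    def test_reverse_complemented_assembly_minus_strand(self, rng):
        truth = random_dna(rng, 4_000)
        (seg,) = ev.align_to_truth(revcomp(truth), truth)
        assert seg.strand == "-" and seg.events == []

    def test_substitution_event_position(self, rng):
        truth = random_dna(rng, 3_000)
        asm = truth[:1_500] + {"A": "C", "C": "G", "G": "T", "T": "A"}[truth[1_500]] + truth[1_501:]
        (seg,) = ev.align_to_truth(asm, truth)
        subs = [e for e in seg.events if e.kind == "SUB"]
        assert len(subs) == 1 and subs[0].tpos == 1_500


class TestCallErrors:
    def test_identical_pair_all_zero(self, rng):
        seq = random_dna(rng, 10_000)
        report = ev.call_errors(ev.align_to_truth(seq, seq), seq)
        assert report.total_error_pct == 0.0
        assert report.large_false_sv_count == 0

    def test_single_substitution_pct(self, rng):
        truth = random_dna(rng, 10_000)
        asm = truth[:5_000] + {"A": "C", "C": "G", "G": "T", "T": "A"}[truth[5_000]] + truth[5_001:]
        report = ev.call_errors(ev.align_to_truth(asm, truth), truth)
        assert report.base_call_error_pct == pytest.approx(0.01)
        assert report.total_error_pct == pytest.approx(0.01)

    def test_five_bp_deletion_pct(self, rng):
        truth = random_dna(rng, 10_005)
        asm = truth[:5_000] + truth[5_005:]
        report = ev.call_errors(
            ev.align_to_truth(asm, truth), truth, repeat_intervals=[]
        )
        assert report.sv_nonrepeat_pct == pytest.approx(100 * 5 / 10_000)

    @pytest.mark.parametrize("sv_len", [1, 2, 10, 100, 500, 2000])
    def test_planted_indels_recovered_exactly(self, rng, sv_len):
        truth = random_dna(rng, 12_000)
        asm = truth[: 4_000] + truth[4_000 + sv_len :]  # deletion in assembly
        report = ev.call_errors(
            ev.align_to_truth(asm, truth), truth, repeat_intervals=[]
        )
        assert [(r[1], r[2]) for r in report.sv_records] == [("DEL", sv_len)]
        assert report.large_false_sv_count == (1 if sv_len > 1000 else 0)

    def test_min_sv_floor_excludes_small_indels(self, rng):
        truth = random_dna(rng, 8_000)
        asm = truth[:4_000] + truth[4_001:]  # 1 bp deletion
        r1 = ev.call_errors(ev.align_to_truth(asm, truth), truth, min_sv=1, repeat_intervals=[])
        r2 = ev.call_errors(ev.align_to_truth(asm, truth), truth, min_sv=2, repeat_intervals=[])
        assert r1.sv_nonrepeat_pct > 0 and r2.sv_nonrepeat_pct == 0

    def test_repeat_annotation_splits_categories(self, rng):
        truth = random_dna(rng, 6_000) + "A" * 30 + random_dna(rng, 6_000)
        asm = truth[:6_010] + truth[6_015:]  # 5 bp deletion inside the A-run
        report = ev.call_errors(ev.align_to_truth(asm, truth), truth)
        assert report.sv_repeat_pct > 0 and report.sv_nonrepeat_pct == 0.0

    def test_symmetry_of_mismatch_count(self, rng):
        a = random_dna(rng, 6_000)
        b = list(a)
        for pos in (500, 2_000, 4_500):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        r_ab = ev.call_errors(ev.align_to_truth(a, b), b, repeat_intervals=[])
        r_ba = ev.call_errors(ev.align_to_truth(b, a), a, repeat_intervals=[])
        assert r_ab.base_call_error_pct == r_ba.base_call_error_pct

    def test_filled_mask_excluded_from_numerator_and_denominator(self, rng):
        truth = random_dna(rng, 10_000)
        asm = truth[:5_000] + truth[5_000:].lower()  # second half "guide-filled"
        mask = [(0, 5_000, "assembled"), (5_000, 10_000, "filled")]
        report = ev.call_errors(
            ev.align_to_truth(asm.upper(), truth), truth, assembled_mask=mask
        )
        assert report.assembled_length == 5_000


class TestLowComplexity:
    def test_homopolymer_and_tandem_found(self, rng):
        left, mid, right = random_dna(rng, 200), random_dna(rng, 200), random_dna(rng, 200)
        seq = left + "A" * 15 + mid + "ATATATATATAT" + right
        ivs = ev.find_low_complexity(seq)
        a_start = len(left)
        at_start = len(left) + 15 + len(mid)
        assert any(s <= a_start and e >= a_start + 15 for s, e in ivs)
        assert any(s <= at_start and e >= at_start + 12 for s, e in ivs)

    def test_plain_sequence_clean(self, rng):
        # random sequence may contain short accidental runs only
        ivs = ev.find_low_complexity(random_dna(rng, 2_000))
        assert all(e - s < 30 for s, e in ivs)


def make_truth_with_snvs(guide: sf.GuideHaplotype, n=10, seed=0):
    return sf.mutate_to_truth(guide, 0.0, 0.0, [], seed=seed, truth_id="t")


class TestRecovery:
    def test_truth_as_consensus_recovers_everything(self, plain_guide):
        truth = sf.mutate_to_truth(
            plain_guide, 1e-3, 0, [sf.SVSpec("DEL", 40), sf.SVSpec("INS", 25)], seed=5
        )
        rec = ev.recover_novel_variants(truth.sequence, truth, plain_guide)
        assert rec.snv_frac == 1.0 and rec.sv_frac == 1.0

    def test_guide_as_consensus_recovers_nothing(self, plain_guide):
        truth = sf.mutate_to_truth(
            plain_guide, 1e-3, 0, [sf.SVSpec("DEL", 40)], seed=5
        )
        rec = ev.recover_novel_variants(plain_guide.sequence, truth, plain_guide)
        assert rec.n_recovered_snv == 0 and rec.n_recovered_sv == 0

    def test_nine_of_ten_snvs(self, plain_guide):
        truth = sf.mutate_to_truth(plain_guide, 0, 0, [], seed=1)
        # plant exactly 10 SNVs by hand
        rng = np.random.default_rng(3)
        positions = sorted(int(p) for p in rng.choice(np.arange(500, 19_000, 50), 10, replace=False))
        ledger = []
        seq = list(plain_guide.sequence)
        for p in positions:
            ref = seq[p]
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
            ledger.append(sf.Variant(p, "SNV", ref, alt))
            seq[p] = alt
        truth = sf.TruthHaplotype("t", plain_guide.id, "".join(seq), tuple(ledger))
        # consensus reverts one SNV to the guide allele
        reverted = list(truth.sequence)
        reverted[positions[4]] = plain_guide.sequence[positions[4]]
        rec = ev.recover_novel_variants("".join(reverted), truth, plain_guide)
        assert rec.n_novel_snv == 10 and rec.n_recovered_snv == 9
        assert rec.snv_frac == pytest.approx(0.9)

    def test_empty_ledger_reports_nan(self, plain_guide):
        truth = sf.TruthHaplotype("t", plain_guide.id, plain_guide.sequence, ())
        rec = ev.recover_novel_variants(plain_guide.sequence, truth, plain_guide)
        assert math.isnan(rec.snv_frac) and math.isnan(rec.sv_frac)


class TestKmersAndPaf:
    def test_unique_150mer_counting(self):
        read = "ACGT" * 37 + "AC"
        assert ev.unique_kmer_count([read], k=150) == 1
        assert ev.unique_kmer_count([read, read], k=150) == 1
        other = "T" + read[1:]
        assert ev.unique_kmer_count([read, other], k=150) == 2

    def test_empty_alignment_list_empty_file(self, tmp_path):
        path = tmp_path / "x.paf"
        ev.dotplot_export([], path)
        assert path.read_text() == ""

    def test_single_segment_roundtrip(self, tmp_path, rng):
        seq = random_dna(rng, 2_000)
        segs = ev.align_to_truth(seq, seq, qname="q", tname="t")
        path = tmp_path / "x.paf"
        ev.dotplot_export(segs, path)
        line = path.read_text().strip().split("\t")
        assert len(line) == 12
        back = ev.read_paf(path)
        assert len(back) == 1
        s0, s1 = segs[0], back[0]
        assert (s0.qname, s0.qlen, s0.qstart, s0.qend, s0.strand) == (
            s1.qname, s1.qlen, s1.qstart, s1.qend, s1.strand
        )
        assert (s0.tname, s0.tlen, s0.tstart, s0.tend, s0.matches, s0.block_len) == (
            s1.tname, s1.tlen, s1.tstart, s1.tend, s1.matches, s1.block_len
        )
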