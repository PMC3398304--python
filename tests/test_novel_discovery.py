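import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mirdev as md
from mirdev.io_formats import SmallRead
from mirdev.novel_discovery import (
    _PAIR_SCORES,
    _STACK_BONUS,
    big_loop,
    fold_stacking_dp,
    has_homopolymer,
    has_tandem_repeat,
    terminal_loops,
)

from oracles import enumerate_fold_score, rc


def sread(seq, count=1, rid="r"):
    return SmallRead(sequence=seq, count=count, stage="BL", read_id=rid)


class TestFolding:
    def test_homopolymer_folds_to_all_dots_zero_energy(self):
        structure, energy = md.fold_hairpin("A" * 80)
        assert structure == "." * 80 and energy == 0.0

    def test_strong_hairpin_core_pairs_and_negative_energy(self):
        seq = "GGGGG" + "AAAAA" + "CCCCC"
        seq = "ACACA" + seq * 3 + "ACACA"  # pad to >= 40 nt
        structure, energy = md.fold_hairpin(seq)
        assert structure.count("(") >= 5 and energy < 0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            md.fold_hairpin("ACGT" * 5)

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            md.fold_hairpin("ACGTN" * 10)

    @pytest.mark.parametrize("seed", range(6))
    def test_stacking_dp_matches_enumeration_oracle(self, seed):
        """DP score equals exhaustive enumeration over all nested
        structures with the same pair/stack weights."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 15))))
        _structure, score = fold_stacking_dp(seq)
        assert score == pytest.approx(
            enumerate_fold_score(seq, _PAIR_SCORES, _STACK_BONUS), abs=1e-9
        )

    def test_dp_on_designed_hairpin_finds_the_stem(self):
        seq = "GGGCGC" + "AAAA" + "GCGCCC"
        structure, score = fold_stacking_dp(seq)
        assert structure.count("(") >= 5 and score < 0

    @given(st.text(alphabet="ACGT", min_size=40, max_size=60))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_energy_never_positive(self, seq):
        _s, e = md.fold_hairpin(seq)
        assert e <= 0.0

    def test_palindromic_construct_pair_count_symmetric(self):
        rng = np.random.default_rng(3)
        arm = "".join(rng.choice(list("ACGT"), size=18))
        s = arm + "AACAA" + rc(arm)
        st1, _ = md.fold_hairpin(s)
        st2, _ = md.fold_hairpin(rc(s))
        assert st1.count("(") == st2.count("(")


class TestStructureParsing:
    def test_single_terminal_loop(self):
        assert terminal_loops("(((....)))") == [(3, 7)]
        assert big_loop("(((....)))") == (3, 7)

    def test_two_terminal_loops(self):
        s = "((...))..((...))"
        assert len(terminal_loops(s)) == 2
        assert big_loop(s) is None

    def test_homopolymer_and_tandem_repeat_detectors(self):
        assert has_homopolymer("ACG" + "T" * 8 + "ACG")
        assert not has_homopolymer("ACG" + "T" * 7 + "ACG")
        assert has_tandem_repeat("ACGTCC" * 2 + "AAA")     # 12 nt, unit 6
        assert has_tandem_repeat("AT" * 6 + "GGCC")        # 12 nt, unit 2
        assert not has_tandem_repeat("ACGTACGGTCAGTCCAGT")


class TestScanGates:
    def test_40nt_perfect_hairpin_rejected_by_length(self):
        rng = np.random.default_rng(5)
        arm = "".join(rng.choice(list("ACGT"), size=16))
        seq = arm + "AACAACAA" + rc(arm)  # 40 nt
        assert md.scan_hairpin_candidates([("x", seq)]) == []

    def test_86nt_hairpin_with_75_percent_gc_rejected(self):
        from mirdev.synthetic_data import _design_hairpin
        rng = np.random.default_rng(6)
        seq = _design_hairpin(rng, stem=31, loop=10, gc=1.0)
        gc = 100 * sum(seq.count(b) for b in "GC") / len(seq)
        assert gc > 70
        assert md.scan_hairpin_candidates([("x", seq)]) == []

    def test_balanced_strong_hairpin_accepted(self):
        from mirdev.synthetic_data import _design_hairpin
        rng = np.random.default_rng(7)
        seq = _design_hairpin(rng, stem=31, loop=10, gc=0.5)
        cands = md.scan_hairpin_candidates([("x", seq)])
        assert len(cands) == 1
        c = cands[0]
        assert c.energy < -25 and 30 <= c.gc_percent <= 70
        assert len(terminal_loops(c.structure)) == 1


class TestDeduplicate:
    def make_candidate(self, seq, source="c1"):
        return md.HairpinCandidate(
            source_id=source, sequence=seq, structure="." * len(seq),
            energy=-30.0, gc_percent=50.0, loop_interval=(30, 40),
        )

    def test_identical_to_known_precursor_is_known_matched(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        known, novel = md.deduplicate_candidates(
            [self.make_candidate(seq)], [("hp-known", seq)]
        )
        assert len(known) == 1 and novel == []

    def test_high_mismatch_density_is_not_matched(self):
        # 2 mismatches inside every 14-nt window of a 20-nt overlap
        rng = np.random.default_rng(12)
        base = "".join(rng.choice(list("ACGT"), size=80))
        mutated = list(base)
        for i in range(0, 80, 6):
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        known, novel = md.deduplicate_candidates(
            [self.make_candidate("".join(mutated))], [("hp", base)]
        )
        assert known == [] and len(novel) == 1

    def test_exact_self_duplicates_collapse_to_one(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        known, novel = md.deduplicate_candidates(
            [self.make_candidate(seq, "a"), self.make_candidate(seq, "b")],
            [],
        )
        assert known == [] and len(novel) == 1


class TestValidateByReads:
    def candidate(self):
        from mirdev.synthetic_data import _design_hairpin
        rng = np.random.default_rng(15)
        seq = _design_hairpin(rng, stem=31, loop=10, gc=0.5)
        return md.scan_hairpin_candidates([("x", seq)])[0]

    def test_50_reads_rejected_51_accepted_boundary(self):
        c = self.candidate()
        frag = c.sequence[2:24]
        _, ok50 = md.validate_by_reads(c, [sread(frag, count=50)])
        _, ok51 = md.validate_by_reads(c, [sread(frag, count=51)])
        assert not ok50 and ok51

    def test_reads_inside_loop_rejected(self):
        c = self.candidate()
        lo, _hi = c.loop_interval
        frag = c.sequence[lo - 2:lo + 16]
        updated, ok = md.validate_by_reads(c, [sread(frag, count=100)])
        assert updated.support_reads == 100 and not ok

    def test_start_positions_within_one_pool_together(self):
        c = self.candidate()
        reads = [sread(c.sequence[2:24], count=30, rid="a"),
                 sread(c.sequence[3:25], count=30, rid="b")]
        updated, ok = md.validate_by_reads(c, reads)
        assert updated.support_reads == 60 and ok

    def test_adding_reads_never_revokes_acceptance(self):
        c = self.candidate()
        frag = c.sequence[2:24]
        _, ok = md.validate_by_reads(c, [sread(frag, count=60)])
        more = [sread(frag, count=60),
                sread(c.sequence[40:60], count=10, rid="x")]
        _, ok_more = md.validate_by_reads(c, more)
        assert ok and ok_more


class TestHomologVariants:
    MATURE = "TGGAATGTAAAGAAGTATGTAT"

    def refs(self):
        return [md.MatureRef(name="miR-known", sequence=self.MATURE)]

    def test_antisense_with_one_mismatch_and_extension_called(self):
        r = list(rc(self.MATURE))
        r[10] = "A" if r[10] != "A" else "C"
        seq = "".join(r) + "CT"
        calls = md.detect_homolog_variants([sread(seq, count=5000)],
                                           self.refs())
        assert len(calls) == 1
        assert calls[0].orientation == "antisense"
        assert calls[0].total_reads == 5000

    def test_exactly_1000_reads_is_no_call_1001_is_called(self):
        r = list(rc(self.MATURE))
        r[10] = "A" if r[10] != "A" else "C"
        seq = "".join(r) + "CT"
        assert md.detect_homolog_variants([sread(seq, count=1000)],
                                          self.refs()) == []
        assert len(md.detect_homolog_variants([sread(seq, count=1001)],
                                              self.refs())) == 1

    def test_sense_seed_variant_with_two_seed_mismatches_called(self):
        s = list(self.MATURE)
        s[2] = "C" if s[2] != "C" else "G"
        s[6] = "C" if s[6] != "C" else "G"
        calls = md.detect_homolog_variants([sread("".join(s), count=2000)],
                                           self.refs())
        assert calls and calls[0].orientation == "sense"
        assert calls[0].seed_mismatches == 2

    def test_three_seed_mismatches_is_no_call(self):
        s = list(self.MATURE)
        for i in (2, 4, 6):
            s[i] = "C" if s[i] != "C" else "G"
        assert md.detect_homolog_variants([sread("".join(s), count=2000)],
                                          self.refs()) == []

    def test_mismatch_outside_seed_is_no_call(self):
        s = list(self.MATURE)
        s[15] = "C" if s[15] != "C" else "G"
        assert md.detect_homolog_variants([sread("".join(s), count=2000)],
                                          self.refs()) == []

    def test_planted_antisense_recovered_with_no_false_positives(
            self, small_scenario, small_pipeline):
        """The planted antisense locus is called; no other locus is."""
        sc = small_scenario
        as_reads = [a.read for a in small_pipeline.legitimacy.antisense]
        as_reads += small_pipeline.unassigned
        guides = [m for m in sc.refs[0] if not m.name.endswith("*")]
        calls = md.detect_homolog_variants(as_reads, guides, min_total=100)
        planted = sc.truth.antisense_fraction.index[0]
        called = {c.nearest_mature for c in calls
                  if c.orientation == "antisense"}
        assert called == {planted}
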