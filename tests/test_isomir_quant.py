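import numpy as np
import pandas as pd
import pytest

import mirdev as md
from mirdev.io_formats import MatureRef, PrecursorRef, SmallRead, StageSet, ValidationError
from mirdev.synthetic_data import (
    default_class_assignment,
    make_reference_set,
    make_stage_profiles,
    simulate_reads,
)

MATURE = "TGGAATGTAAAGAAGTATGT"
# precursor: 3 nt upstream flank, mature, then "AG..." downstream flank
PRE = "CCG" + MATURE + "AGTTTTTTCTACATACTTCTTTACATTCCAGC"


@pytest.fixture()
def mref():
    return MatureRef(name="miR-t", sequence=MATURE, hairpin_name="hp-t")


@pytest.fixture()
def precursor():
    return PrecursorRef(name="hp-t", sequence=PRE,
                        mature_start=3, mature_end=3 + len(MATURE))


def assignment(mref, seq, fp=0, tp=0, stage="BL", count=1):
    return md.Assignment(
        read=SmallRead(sequence=seq, count=count, stage=stage, read_id="r"),
        ref=mref, five_prime_offset=fp, three_prime_offset=tp,
        mismatches=(), strand="sense",
    )


class TestClassifyIsomir:
    def test_canonical_read_has_zero_offsets_and_empty_tail(self, mref,
                                                            precursor):
        c = md.classify_isomir(assignment(mref, MATURE), precursor)
        assert c.key == ("miR-t", 0, 0, "")
        assert c.tail_status == "" and c.head_seq == ""

    def test_tail_base_matching_precursor_flank_is_templated(self, mref,
                                                             precursor):
        # downstream flank begins with "AG": mature+"A" is templated
        c = md.classify_isomir(assignment(mref, MATURE + "A", tp=1), precursor)
        assert c.tail_seq == "A" and c.tail_status == "t"

    def test_tail_base_not_in_precursor_flank_is_untemplated(self, mref,
                                                             precursor):
        c = md.classify_isomir(assignment(mref, MATURE + "T", tp=1), precursor)
        assert c.tail_seq == "T" and c.tail_status == "u"

    def test_mixed_tail_labelled_per_base(self, mref, precursor):
        c = md.classify_isomir(assignment(mref, MATURE + "AT", tp=2),
                               precursor)
        assert c.tail_status == "tu"  # A matches flank "AG"[0], T does not

    def test_without_precursor_status_is_unknown(self, mref):
        c = md.classify_isomir(assignment(mref, MATURE + "A", tp=1), None)
        assert c.tail_status == "?"

    def test_head_addition_checked_against_upstream_flank(self, mref,
                                                          precursor):
        c = md.classify_isomir(assignment(mref, "G" + MATURE, fp=1), precursor)
        assert c.head_seq == "G" and c.head_status == "t"  # PRE[2] == "G"
        c2 = md.classify_isomir(assignment(mref, "T" + MATURE, fp=1),
                                precursor)
        assert c2.head_status == "u"

    def test_inconsistent_precursor_coordinates_raise(self, mref):
        bad = PrecursorRef(name="hp-t", sequence="A" * 60, mature_start=0,
                           mature_end=20)
        with pytest.raises(ValidationError, match="not found"):
            md.classify_isomir(assignment(mref, MATURE), bad)


class TestFrequencyTable:
    def table_from(self, counts, stages):
        """counts: {(fp, tp, tail): per-stage list} for one miRNA."""
        mref = MatureRef(name="miR-t", sequence=MATURE)
        classified = []
        for (fp, tp, tail), per_stage in counts.items():
            for stage, c in zip(stages, per_stage):
                if c:
                    classified.append(md.ClassifiedRead(
                        mirna="miR-t", five_prime_offset=fp,
                        three_prime_offset=tp, tail_seq=tail,
                        tail_status="t" * len(tail), head_seq="",
                        head_status="", stage=stage, count=c,
                    ))
        return md.build_isomir_table(classified, stages)

    def test_relative_frequencies_from_counts(self, stages):
        tab = self.table_from({
            (0, 0, ""): [700] + [0] * 7,
            (0, 1, "A"): [250] + [0] * 7,
            (0, -1, ""): [50] + [0] * 7,
        }, stages)
        freq = md.isomir_relative_frequency(tab, stages)
        bl = freq["BL"].droplevel("tail_seq")
        assert bl[("miR-t", 0, 0)] == pytest.approx(0.70)
        assert bl[("miR-t", 0, 1)] == pytest.approx(0.25)
        assert bl[("miR-t", 0, -1)] == pytest.approx(0.05)

    def test_single_isomir_has_frequency_one(self, stages):
        tab = self.table_from({(0, 0, ""): [10] * 8}, stages)
        freq = md.isomir_relative_frequency(tab, stages)
        assert (freq.values == 1.0).all()

    def test_zero_total_stage_is_nan_not_zero(self, stages):
        tab = self.table_from({(0, 0, ""): [10, 0, 10, 10, 10, 10, 10, 10]},
                              stages)
        freq = md.isomir_relative_frequency(tab, stages)
        assert np.isnan(freq["EP"]).all()

    def test_frequencies_sum_to_one_where_defined(self, small_pipeline,
                                                  stages):
        tab = small_pipeline.isomir_table
        freq = md.isomir_relative_frequency(tab, stages)
        sums = freq.groupby(level="mirna").sum()
        counts = tab[list(stages)].groupby(level="mirna").sum()
        defined = counts > 0
        assert np.allclose(sums.values[defined.values], 1.0, atol=1e-9)

    def test_count_conservation_against_retained_assignments(
            self, small_pipeline, stages):
        """isomiR stage counts sum to the miRNA's retained counts."""
        per_mirna = {}
        for a in small_pipeline.legitimacy.retained:
            key = (a.ref.name, a.read.stage)
            per_mirna[key] = per_mirna.get(key, 0) + a.read.count
        tab = small_pipeline.isomir_table[list(stages)]
        sums = tab.groupby(level="mirna").sum()
        for (mirna, stage), total in per_mirna.items():
            assert sums.loc[mirna, stage] == total

    def test_negative_counts_rejected(self, stages):
        tab = self.table_from({(0, 0, ""): [10] * 8}, stages)
        tab.iloc[0, 0] = -1
        with pytest.raises(ValidationError):
            md.isomir_relative_frequency(tab, stages)


class TestSelection:
    def make_table(self, stages, rows):
        """rows: list of (mirna, fp, tp, tail, total, peak_freq_stage_count)"""
        classified = []
        for mirna, fp, tp, tail, per_stage in rows:
            for stage, c in zip(stages, per_stage):
                if c:
                    classified.append(md.ClassifiedRead(
                        mirna=mirna, five_prime_offset=fp,
                        three_prime_offset=tp, tail_seq=tail,
                        tail_status="t" * len(tail), head_seq="",
                        head_status="", stage=stage, count=c,
                    ))
        return md.build_isomir_table(classified, stages)

    def test_exactly_1000_reads_is_excluded_strict(self, stages):
        tab = self.make_table(stages, [
            ("miR-a", 0, 0, "", [8000] + [0] * 7),
            ("miR-a", 0, 1, "A", [1000] + [0] * 7),   # f > 0.05, reads = 1000
        ])
        kept = md.select_isomirs_for_profiling(tab, stages)
        assert (0, 1) not in [
            (i[1], i[2]) for i in kept.index
        ]

    def test_frequency_exactly_005_everywhere_is_excluded_strict(self, stages):
        tab = self.make_table(stages, [
            ("miR-a", 0, 0, "", [95000] + [0] * 7),
            ("miR-a", 0, 1, "A", [5000] + [0] * 7),   # f = 0.05 exactly
        ])
        kept = md.select_isomirs_for_profiling(tab, stages)
        assert (0, 1) not in [(i[1], i[2]) for i in kept.index]

    def test_1001_reads_and_f_006_is_included(self, stages):
        tab = self.make_table(stages, [
            ("miR-a", 0, 0, "", [15682] + [0] * 7),
            ("miR-a", 0, 1, "A", [1001] + [0] * 7),   # f = 0.06, reads 1001
        ])
        kept = md.select_isomirs_for_profiling(tab, stages)
        assert (0, 1) in [(i[1], i[2]) for i in kept.index]

    def test_only_top_n_mirnas_kept(self, stages):
        rows = [(f"miR-{chr(97 + i)}", 0, 0, "",
                 [3000 * (i + 1)] + [0] * 7) for i in range(5)]
        tab = self.make_table(stages, rows)
        kept = md.select_isomirs_for_profiling(tab, stages, top_n_mirnas=2)
        assert set(kept.index.get_level_values("mirna")) == {"miR-d", "miR-e"}

    def test_five_prime_shift_beyond_plus_one_excluded(self, stages):
        tab = self.make_table(stages, [
            ("miR-a", 0, 0, "", [10000] + [0] * 7),
            ("miR-a", 2, 0, "", [5000] + [0] * 7),
        ])
        kept = md.select_isomirs_for_profiling(tab, stages)
        assert 2 not in kept.index.get_level_values("five_prime_offset")


class TestTailComposition:
    def test_ten_percent_untemplated_u(self):
        classified = [
            md.ClassifiedRead(mirna="miR-a", five_prime_offset=0,
                              three_prime_offset=0, tail_seq="",
                              tail_status="", head_seq="", head_status="",
                              stage="BL", count=90),
            md.ClassifiedRead(mirna="miR-a", five_prime_offset=0,
                              three_prime_offset=1, tail_seq="T",
                              tail_status="u", head_seq="", head_status="",
                              stage="BL", count=10),
        ]
        stats = md.tail_composition_stats(classified)
        row = stats[(stats.base == "U") & (stats.status == "untemplated")
                    & (stats.end == "3p")].iloc[0]
        assert row["pct_reads"] == pytest.approx(10.0)

    def test_no_additions_yields_empty_table(self):
        classified = [
            md.ClassifiedRead(mirna="miR-a", five_prime_offset=0,
                              three_prime_offset=0, tail_seq="",
                              tail_status="", head_seq="", head_status="",
                              stage="BL", count=100),
        ]
        assert len(md.tail_composition_stats(classified)) == 0

    def test_planted_au_bias_recovered_and_labels_exact(self):
        """Planted untemplated A:U = 60:40 is recovered within 3 SE and
        template labels agree with direct precursor lookup everywhere."""
        refs = make_reference_set(3, 71)
        guides = [m.name for m in refs[0] if not m.name.endswith("*")]
        model = md.IsomirModel(
            offset_probs={(0, 0): 0.4, (0, 1): 0.4, (0, 2): 0.2},
            tail_alphabet_probs={"A": 0.6, "T": 0.4},
            untemplated_prob=1.0,
        )
        truth = make_stage_profiles(
            refs, StageSet(), default_class_assignment(guides), 4000, 72,
            isomir_model=model, star_fraction=0.0,
        )
        reads, _ = simulate_reads(truth, refs, contaminant_fraction=0.0,
                                  seed=73, error_rate=0.0)
        pipe = md.run_pipeline(reads, refs, [("c", "G" * 40)], StageSet())
        stats = md.tail_composition_stats(pipe.classified)
        ut = stats[(stats.end == "3p") & (stats.status == "untemplated")]
        occ = ut.groupby("base")["base_occurrences"].sum()
        n = occ.sum()
        frac_a = occ.get("A", 0) / n
        assert abs(frac_a - 0.6) <= 3 * np.sqrt(0.6 * 0.4 / n)
        # no templated 3' additions exist under untemplated_prob = 1 with
        # G/C-flanked precursors
        assert not len(stats[(stats.end == "3p")
                             & (stats.status == "templated")])
        # label agreement with brute-force precursor lookup
        pre = {p.name: p for p in refs[1]}
        mat = {m.name: m for m in refs[0]}
        for c in pipe.classified:
            hp = pre[mat[c.mirna].hairpin_name]
            start = hp.sequence.find(mat[c.mirna].sequence)
            end = start + len(mat[c.mirna].sequence)
            for k, (base, st) in enumerate(zip(c.tail_seq, c.tail_status)):
                expect = "t" if hp.sequence[end + k] == base else "u"
                assert st == expect
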