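import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import brute_find_ssrs
from radmarkers.ssr import (SSRLocus, canonical_motif, find_ssrs, revcomp,
                            ssr_summary)

FLANK_L = "GCAGCTGGAGCGCCTGAGCC"   # repeat-free 20-mers
FLANK_R = "GGCTCAGGCGCTCCAGCTGC"


class TestFindSSRs:
    def test_dinucleotide_at_threshold(self):
        loci = find_ssrs(FLANK_L + "AT" * 7 + FLANK_R)
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.motif, l.unit_len, l.repeats) == \
            (21, 34, "AT", 2, 7)
        assert l.canonical_class == "AT/AT"
        assert l.end - l.start + 1 == l.unit_len * l.repeats

    def test_below_threshold_yields_nothing(self):
        assert find_ssrs(FLANK_L + "AT" * 6 + FLANK_R) == []

    @pytest.mark.parametrize("motif,reps,found", [
        ("ACT", 5, True), ("ACT", 4, False),
        ("ACGT", 4, True), ("ACGT", 3, False),
        ("AACGT", 3, True), ("AACGT", 2, False),
        ("AACGTC", 3, True), ("AACGTCG", 3, True), ("AACGTCGG", 3, True),
    ])
    def test_per_unit_length_minima(self, motif, reps, found):
        loci = find_ssrs(FLANK_L + motif * reps + FLANK_R)
        assert bool(loci) is found
        if found:
            # the observed motif may be a rotation when the flank boundary
            # happens to extend the run; unit length and class are invariant
            assert loci[0].unit_len == len(motif)
            assert loci[0].repeats == reps
            assert loci[0].canonical_class == canonical_motif(motif)

    def test_compound_grouping_within_gap(self):
        # fixed 100 bp repeat-free spacer (verified SSR-free)
        spacer = ("AGGATACACACTCTCCTTTTAGCAATTACGAGCTGATTAGTAAAACAGCA"
                  "CAACAGCTAGGTGTCAATAGGCCTCTTCGGGACGTAGTTAGCCAGACCGC")
        assert find_ssrs(spacer) == []
        seq = FLANK_L + "AAT" * 5 + spacer + "AG" * 8 + FLANK_R
        loci = find_ssrs(seq, compound_gap=500)
        assert len(loci) == 2
        assert loci[0].compound_id is not None
        assert loci[0].compound_id == loci[1].compound_id
        # same layout with a gap beyond the limit: two independent loci
        loci2 = find_ssrs(seq, compound_gap=99)
        assert [l.compound_id for l in loci2] == [None, None]

    def test_non_primitive_motifs_not_reported_at_longer_period(self):
        # (AT)x8 must come out as a dinucleotide run, never as ATAT repeats
        loci = find_ssrs(FLANK_L + "AT" * 8 + FLANK_R)
        assert [l.unit_len for l in loci] == [2]

    def test_run_containing_n_discarded(self):
        assert find_ssrs(FLANK_L + "ATN" + "AT" * 7) == [] or all(
            "N" not in l.motif for l in find_ssrs(FLANK_L + "ATN" + "AT" * 7))

    def test_empty_contig(self):
        assert find_ssrs("") == []

    def test_agrees_with_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            gc = rng.choice([0.34, 0.5])
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            seq = "".join(rng.choice(list("ACGT"), size=1500, p=p))
            got = [(l.start, l.end, l.motif, l.repeats) for l in find_ssrs(seq)]
            assert got == brute_find_ssrs(seq)


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif,expected", [
        ("TA", "AT/AT"), ("AT", "AT/AT"), ("TTC", "AAG/CTT"),
        ("TGA", "ATC/ATG"), ("AAAAT", "AAAAT/ATTTT"), ("GAA", "AAG/CTT"),
    ])
    def test_published_class_labels(self, motif, expected):
        assert canonical_motif(motif) == expected

    @given(st.text(alphabet="ACGT", min_size=2, max_size=8))
    def test_invariant_under_rotation_and_revcomp(self, motif):
        from radmarkers.ssr import _is_primitive
        if not _is_primitive(motif):
            with pytest.raises(ValueError):
                canonical_motif(motif)
            return
        base = canonical_motif(motif)
        for i in range(len(motif)):
            rot = motif[i:] + motif[:i]
            assert canonical_motif(rot) == base
            assert canonical_motif(revcomp(rot)) == base

    @pytest.mark.parametrize("bad", ["ATAT", "AA", "A", "ACGTACGTA", "ANT"])
    def test_invalid_motifs_rejected(self, bad):
        with pytest.raises(ValueError):
            canonical_motif(bad)


def _locus(start, end, motif, unit_len, reps, compound=None):
    return SSRLocus("c", start, end, motif, unit_len, reps,
                    canonical_motif(motif), compound)


class TestSummary:
    def test_frequency_formatting(self):
        loci = [_locus(1, 14, "AT", 2, 7)]
        s = ssr_summary(loci, 10.0)
        assert s.frequency_kb == 10.0 and s.frequency_label == "1/10.00 kb"

    def test_zero_loci_reports_na(self):
        s = ssr_summary([], 100.0)
        assert s.frequency_kb is None and s.frequency_label == "NA"

    def test_percentages_sum_to_100(self):
        loci = [_locus(i * 100, i * 100 + 13, m, 2, 7)
                for i, m in enumerate(["AT", "AG", "AC"])] + \
               [_locus(1000, 1014, "AACGT", 5, 3)]
        s = ssr_summary(loci, 50.0)
        assert abs(sum(s.unit_len_pct.values()) - 100.0) < 0.05
        assert abs(sum(s.class_pct.values()) - 100.0) < 0.05
        assert s.unit_len_pct[2] == 75.0 and s.unit_len_pct[5] == 25.0

    def test_compound_members_counted(self):
        loci = [_locus(1, 14, "AT", 2, 7, "c1"), _locus(30, 43, "AG", 2, 7, "c1"),
                _locus(500, 513, "AC", 2, 7)]
        assert ssr_summary(loci, 10.0).n_compound == 2
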