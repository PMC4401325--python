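import numpy as np
import pytest

from radmarkers.compare import (FlankIndex, MarkerInconsistencyError,
                                classify_ssr_pair, classify_variant_pair,
                                extract_flanks, match_flanks,
                                partition_markers)
from radmarkers.io import Contig, VariantRecord
from radmarkers.ssr import SSRLocus, canonical_motif
from radmarkers.variants import zygosity


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _ssr_contig(rng, motif, reps, left=60, right=60):
    seq = _rand(rng, left) + motif * reps + _rand(rng, right)
    locus = SSRLocus("", left + 1, left + len(motif) * reps, motif,
                     len(motif), reps, canonical_motif(motif))
    return seq, locus


class TestExtractFlanks:
    def test_coordinates_of_flanks(self, rng):
        seq = _rand(rng, 300)
        locus = SSRLocus("c1", 50, 63, "AT", 2, 7, "AT/AT")
        contigs = {"c1": Contig("c1", seq)}
        fm = extract_flanks(locus, contigs, flank_min=20, flank_max=20,
                            genotype="A")
        assert fm.left_flank == seq[29:49]    # positions 30-49
        assert fm.right_flank == seq[63:83]   # positions 64-83
        assert (fm.start, fm.end, fm.kind) == (50, 63, "SSR")

    def test_snp_site_is_single_base_locus(self, rng):
        seq = _rand(rng, 300)
        rec = VariantRecord("c1", 150, "A" if seq[149] != "A" else "C", "G",
                            30, 60, 0, 99, 0, 30)
        fm = extract_flanks(rec, {"c1": Contig("c1", seq)}, 20, 20)
        assert fm.left_flank == seq[129:149] and fm.right_flank == seq[150:170]
        assert fm.kind == "SNP"

    def test_marker_too_close_to_contig_end_is_unanchorable(self, rng):
        seq = _rand(rng, 100)
        locus = SSRLocus("c1", 10, 23, "AT", 2, 7, "AT/AT")
        assert extract_flanks(locus, {"c1": Contig("c1", seq)}, 20, 200) is None

    def test_n_in_flank_truncates(self, rng):
        seq = _rand(rng, 100) + "N" + _rand(rng, 30) + "AT" * 7 + _rand(rng, 60)
        locus = SSRLocus("c1", 132, 145, "AT", 2, 7, "AT/AT")
        fm = extract_flanks(locus, {"c1": Contig("c1", seq)}, 20, 200)
        assert len(fm.left_flank) == 30 and "N" not in fm.left_flank

    def test_unknown_contig_raises(self):
        locus = SSRLocus("nope", 50, 63, "AT", 2, 7, "AT/AT")
        with pytest.raises(KeyError):
            extract_flanks(locus, {}, 20, 200)


class TestMatchFlanks:
    def _flanked(self, rng, genotype, contig_id, seq, locus):
        locus = SSRLocus(contig_id, locus.start, locus.end, locus.motif,
                         locus.unit_len, locus.repeats, locus.canonical_class)
        return extract_flanks(locus, {contig_id: Contig(contig_id, seq)},
                              20, 200, genotype=genotype)

    def test_identical_flanks_anchor(self, rng):
        seq, locus = _ssr_contig(rng, "AAT", 6)
        fa = self._flanked(rng, "A", "a1", seq, locus)
        fb = self._flanked(rng, "B", "b1", seq, locus)
        partner, n = match_flanks(fa, FlankIndex([fb]))
        assert partner == fb.marker_id and n == 1

    def test_unrelated_flanks_do_not_anchor(self, rng):
        seq_a, locus_a = _ssr_contig(rng, "AAT", 6)
        seq_b, locus_b = _ssr_contig(rng, "AAT", 6)
        fa = self._flanked(rng, "A", "a1", seq_a, locus_a)
        fb = self._flanked(rng, "B", "b1", seq_b, locus_b)
        partner, n = match_flanks(fa, FlankIndex([fb]))
        assert partner is None and n == 0

    def test_one_bad_flank_blocks_anchoring(self, rng):
        # left flanks identical, right flank replaced by unrelated sequence
        left = _rand(rng, 60)
        core = "AAT" * 6
        seq_a = left + core + _rand(rng, 60)
        seq_b = left + core + _rand(rng, 60)
        locus = SSRLocus("", 61, 78, "AAT", 3, 6, canonical_motif("AAT"))
        fa = self._flanked(rng, "A", "a1", seq_a, locus)
        fb = self._flanked(rng, "B", "b1", seq_b, locus)
        partner, _ = match_flanks(fa, FlankIndex([fb]))
        assert partner is None

    def test_reverse_complement_orientation_anchors(self, rng):
        from radmarkers.ssr import revcomp
        seq, locus = _ssr_contig(rng, "AAT", 6)
        fa = self._flanked(rng, "A", "a1", seq, locus)
        rc_seq = revcomp(seq)
        k = len(seq)
        rc_locus = SSRLocus("", k - locus.end + 1, k - locus.start + 1,
                            "ATT", 3, 6, canonical_motif("AAT"))
        fb = self._flanked(rng, "B", "b1", rc_seq, rc_locus)
        partner, _ = match_flanks(fa, FlankIndex([fb]))
        assert partner == fb.marker_id


class TestClassification:
    def _locus(self, motif, reps):
        return SSRLocus("c", 1, len(motif) * reps, motif, len(motif), reps,
                        canonical_motif(motif))

    def test_repeat_count_difference_is_polymorphic(self):
        assert classify_ssr_pair(self._locus("AT", 8), self._locus("AT", 10))
        assert not classify_ssr_pair(self._locus("AT", 8), self._locus("AT", 8))

    def test_class_mismatch_is_inconsistency_not_polymorphism(self):
        with pytest.raises(MarkerInconsistencyError):
            classify_ssr_pair(self._locus("AT", 8), self._locus("AG", 8))

    @pytest.mark.parametrize("ad_a,ad_b,alt_a,alt_b,expected", [
        ((0, 20), (0, 20), "G", "T", True),    # hom G vs hom T
        ((0, 20), (8, 12), "G", "T", False),   # second parent heterozygous
        ((0, 20), (0, 20), "G", "G", False),   # same allele both sides
    ])
    def test_variant_pair_rule(self, ad_a, ad_b, alt_a, alt_b, expected):
        a = VariantRecord("ca", 5, "C", alt_a, 20, 60, 0, 99, *ad_a)
        b = VariantRecord("cb", 5, "C", alt_b, 20, 60, 0, 99, *ad_b)
        got = classify_variant_pair(a, b, zygosity(a), zygosity(b))
        assert got is expected


class TestPartition:
    def _markers(self, rng, n, genotype, prefix):
        out = []
        for i in range(n):
            seq, locus = _ssr_contig(rng, "AAT", 6)
            cid = f"{prefix}{i}"
            locus = SSRLocus(cid, locus.start, locus.end, locus.motif,
                             locus.unit_len, locus.repeats,
                             locus.canonical_class)
            out.append(extract_flanks(
                locus, {cid: Contig(cid, seq)}, 20, 200, genotype=genotype))
        return out

    def test_disjoint_sets_all_parent_specific(self, rng):
        fa = self._markers(rng, 3, "A", "a")
        fb = self._markers(rng, 4, "B", "b")
        res = partition_markers(fa, fb, classify_pair=classify_ssr_pair)
        assert res.counts["shared"] == 0
        assert res.counts["a_only"] == 3 and res.counts["b_only"] == 4
        assert res.counts["candidates"] == 7

    def test_identical_sets_fully_shared_with_zero_candidates(self, rng):
        seqs = []
        for i in range(3):
            seq, locus = _ssr_contig(rng, "AAT", 6)
            seqs.append((seq, locus))
        def build(genotype, prefix):
            out = []
            for i, (seq, locus) in enumerate(seqs):
                cid = f"{prefix}{i}"
                l = SSRLocus(cid, locus.start, locus.end, locus.motif,
                             locus.unit_len, locus.repeats,
                             locus.canonical_class)
                out.append(extract_flanks(l, {cid: Contig(cid, seq)}, 20, 200,
                                          genotype=genotype))
            return out
        res = partition_markers(build("A", "a"), build("B", "b"),
                                classify_pair=classify_ssr_pair)
        assert res.counts["shared"] == 3
        assert res.counts["insilico_poly"] == 0
        assert res.counts["candidates"] == 0
        # partition identity: every marker in exactly one status
        covered = (res.counts["shared"] + res.counts["a_only"]
                   + res.counts["b_only"] + res.counts["unanchorable"])
        assert covered == 3 + 3 - res.counts["shared"]

    def test_anchoring_is_symmetric_on_clean_pairs(self, rng):
        fa = self._markers(rng, 3, "A", "a")
        # B set: same contigs as A (copy), so mutual best must pair them 1:1
        fb = []
        for fm in fa:
            fb.append(type(fm)(
                marker_id=fm.marker_id.replace("A:", "B:"), genotype="B",
                kind=fm.kind, contig_id=fm.contig_id, start=fm.start,
                end=fm.end, left_flank=fm.left_flank,
                right_flank=fm.right_flank, payload=fm.payload))
        res = partition_markers(fa, fb, classify_pair=classify_ssr_pair)
        assert res.counts["shared"] == 3
        for a_id, b_id in res.pairs:
            assert a_id.replace("A:", "B:") == b_id
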