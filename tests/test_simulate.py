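import numpy as np
import pytest

from radmarkers.simulate import (SimulationConfig, emit_variant_calls,
                                 evaluate_recovery, generate_parents,
                                 known_db_fixture, _rand_seq)
from radmarkers.ssr import find_ssrs
from radmarkers.variants import indel_hard_filter, tstv_ratio


def _tiny(seed=5, **overrides):
    base = dict(seed=seed, n_ssr_shared_equal=4, n_ssr_shared_divergent=3,
                n_ssr_a_only=2, n_ssr_b_only=2, n_snp=6, n_indel=5,
                n_background=2)
    base.update(overrides)
    return SimulationConfig(**base)


class TestGenerateParents:
    def test_deterministic_for_fixed_seed(self):
        a1, b1, t1 = generate_parents(_tiny())
        a2, b2, t2 = generate_parents(_tiny())
        assert [(c.id, c.sequence) for c in a1] == [(c.id, c.sequence) for c in a2]
        assert [(c.id, c.sequence) for c in b1] == [(c.id, c.sequence) for c in b2]
        assert t1 == t2

    def test_all_counts_zero_gives_empty_truth(self):
        a, b, t = generate_parents(_tiny(
            n_ssr_shared_equal=0, n_ssr_shared_divergent=0, n_ssr_a_only=0,
            n_ssr_b_only=0, n_snp=0, n_indel=0, n_background=2))
        assert t == []
        assert len(a) == 2 and len(b) == 2   # background only

    def test_planted_ssrs_are_the_only_ssrs(self):
        a, b, truth = generate_parents(_tiny())
        planted = {(r.contig_a, r.start_a, r.end_a) for r in truth
                   if r.kind.startswith("ssr") and r.contig_a}
        found = set()
        for c in a:
            for l in find_ssrs(c):
                found.add((c.id, l.start, l.end))
        assert found == planted

    def test_divergent_pairs_differ_only_in_repeat_count(self):
        a, b, truth = generate_parents(_tiny())
        amap = {c.id: c.sequence for c in a}
        bmap = {c.id: c.sequence for c in b}
        for r in truth:
            if r.kind != "ssr_divergent":
                continue
            assert r.reps_a != r.reps_b
            sa, sb = amap[r.contig_a], bmap[r.contig_b]
            # identical flanks either side of the repeat run
            assert sa[:r.start_a - 1] == sb[:r.start_b - 1]
            assert sa[r.end_a:] == sb[r.end_b:]

    def test_gc_content_near_target(self):
        rng = np.random.default_rng(9)
        seq = _rand_seq(rng, 1_000_000, 0.34)
        gc = sum(1 for ch in seq if ch in "GC") / len(seq)
        assert abs(gc - 0.34) < 0.01


class TestEmitVariantCalls:
    def test_reciprocal_tables_swap_ref_and_alt(self):
        cfg = _tiny()
        _, _, truth = generate_parents(cfg)
        ab, ba = emit_variant_calls(truth, cfg)
        by_ab = {(r.contig_id, r.pos): r for r in ab}
        for row in truth:
            if row.kind not in ("snp", "indel"):
                continue
            rec = by_ab[(row.contig_b, row.pos_ab)]
            assert (rec.ref, rec.alt) == (row.ref_ab, row.alt_ab)
            assert (row.ref_ba, row.alt_ba) == (rec.alt, rec.ref)

    def test_noiseless_records_all_pass_filters_and_are_hom(self):
        cfg = _tiny()
        _, _, truth = generate_parents(cfg)
        ab, ba = emit_variant_calls(truth, cfg)
        from radmarkers.variants import snp_depth_filter, zygosity
        for rec in ab + ba:
            if rec.vtype == "SNP":
                assert snp_depth_filter(rec).keep
            else:
                assert indel_hard_filter(rec).keep
            assert zygosity(rec).call == "HOM"

    def test_forced_depth_failures_match_requested_count(self):
        cfg = _tiny(n_indel=10, frac_indel_fail_dp=0.3)
        _, _, truth = generate_parents(cfg)
        ab, _ = emit_variant_calls(truth, cfg)
        indels = [r for r in ab if r.vtype != "SNP"]
        removed = [r for r in indels if not indel_hard_filter(r).keep]
        assert len(removed) == 3
        assert all(indel_hard_filter(r).reason == "DP<5" for r in removed)

    def test_tstv_of_planted_snps_near_target(self):
        cfg = SimulationConfig(seed=2, n_ssr_shared_equal=0,
                               n_ssr_shared_divergent=0, n_ssr_a_only=0,
                               n_ssr_b_only=0, n_snp=2000, n_indel=0,
                               n_background=0)
        _, _, truth = generate_parents(cfg)
        ab, _ = emit_variant_calls(truth, cfg)
        assert tstv_ratio(ab) == pytest.approx(1.76, abs=0.25)


class TestKnownDbFixture:
    def test_overlap_fraction_marks_expected_rows(self):
        cfg = _tiny()
        _, _, truth = generate_parents(cfg)
        db = known_db_fixture(truth, 0.5, seed=cfg.seed)
        eligible = [r for r in truth
                    if r.kind in ("ssr_divergent", "ssr_a_only", "ssr_b_only")]
        marked = [r for r in eligible if r.expected_redundant]
        assert len(marked) == round(0.5 * len(eligible))
        assert len(db.records) == len(marked) + cfg.known_db_extra

    @pytest.mark.parametrize("frac,n_marked", [(0.0, 0), (1.0, 7)])
    def test_extreme_fractions(self, frac, n_marked):
        cfg = _tiny()
        _, _, truth = generate_parents(cfg)
        known_db_fixture(truth, frac, seed=1)
        eligible = [r for r in truth
                    if r.kind in ("ssr_divergent", "ssr_a_only", "ssr_b_only")]
        assert sum(1 for r in eligible if r.expected_redundant) == n_marked


class TestRecovery:
    def test_small_noiseless_run_recovers_truth_exactly(self, small_sim):
        rec = evaluate_recovery(small_sim["result"], small_sim["truth"])
        assert rec["mismatches"] == []
        assert rec["recovery_pct"] == 100.0
        counts = small_sim["result"].ssr_partition.counts
        cfg = small_sim["sim_cfg"]
        assert counts["insilico_poly"] == cfg.n_ssr_shared_divergent
        assert counts["shared"] == (cfg.n_ssr_shared_equal
                                    + cfg.n_ssr_shared_divergent)
        assert counts["a_only"] == cfg.n_ssr_a_only
        assert counts["b_only"] == cfg.n_ssr_b_only
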