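"""Synthetic dual-parent data with a planted, fully tracked truth table.

Emulates the statistical structure of a reduced-representation (RAD-seq)
parental contig pair: ~34% GC contigs of 200-800 bp, SSR loci with the
observed motif-size spectrum, SNPs at a 1.76 transition/transversion ratio,
short InDels with geometric lengths (mean 1.4 bp), and caller-style site
metrics.  Every planted feature carries its expected downstream outcome
(anchoring status, in-silico polymorphism, zygosity call, filter decision,
redundancy flag), so the whole pipeline can be verified end to end with no
external data.  Reads are never simulated: the generator emits the variant
tables a caller would produce, which keeps the verification surface exact.

Noise is layered and independently switchable; with all noise fractions at
zero (the default) the pipeline must recover the truth table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import Contig, VariantRecord
from .redundancy import KnownMarkerDB
from .ssr import DEFAULT_MINIMA, canonical_motif, find_ssrs

# Table-2-style motif-size spectrum (fraction of SSRs per unit length)
DEFAULT_MOTIF_WEIGHTS = {2: 0.190, 3: 0.178, 4: 0.124, 5: 0.333,
                         6: 0.139, 7: 0.031, 8: 0.005}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the emulated ones."""

    seed: int = 0
    gc_target: float = 0.34
    contig_len_min: int = 200
    contig_len_max: int = 800
    n_ssr_shared_equal: int = 100
    n_ssr_shared_divergent: int = 50
    n_ssr_a_only: int = 60
    n_ssr_b_only: int = 60
    motif_weights: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_WEIGHTS))
    n_snp: int = 500
    tstv_target: float = 1.76
    n_indel: int = 200
    indel_mean_len: float = 1.4
    n_background: int = 30
    depth_mean: float = 30.0
    # independently switchable noise layers (all zero = noiseless)
    frac_het: float = 0.0            # shared sites planted heterozygous
    frac_unknown: float = 0.0        # shared sites in the MAF grey zone
    frac_indel_fail_mq0: float = 0.0
    frac_indel_fail_mq: float = 0.0
    frac_indel_fail_qual: float = 0.0
    frac_indel_fail_dp: float = 0.0
    frac_snp_low_depth: float = 0.0
    known_db_overlap: float = 0.5
    known_db_extra: int = 20

    def validate(self) -> None:
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must lie in (0, 1)")
        if self.tstv_target <= 0:
            raise ValueError("tstv_target must be positive")
        for name in ("n_ssr_shared_equal", "n_ssr_shared_divergent",
                     "n_ssr_a_only", "n_ssr_b_only", "n_snp", "n_indel",
                     "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthRow:
    """Expected pipeline outcome for one planted feature."""

    feature_id: str
    kind: str                       # ssr_shared_equal | ssr_divergent |
                                    # ssr_a_only | ssr_b_only | snp | indel
    contig_a: str | None = None
    contig_b: str | None = None
    start_a: int | None = None
    end_a: int | None = None
    start_b: int | None = None
    end_b: int | None = None
    motif: str | None = None
    canonical_class: str | None = None
    reps_a: int | None = None
    reps_b: int | None = None
    pos_ab: int | None = None       # record in the A-vs-B table (on contig_b)
    ref_ab: str | None = None
    alt_ab: str | None = None
    pos_ba: int | None = None       # record in the B-vs-A table (on contig_a)
    ref_ba: str | None = None
    alt_ba: str | None = None
    zyg: str | None = None          # planted zygosity class (both directions)
    filter_ab: str | None = None    # "KEEP" or "REMOVE:<reason>"
    filter_ba: str | None = None
    expected_status: str | None = None   # SHARED / A_ONLY / B_ONLY (pair view)
    expected_poly: bool = False
    expected_redundant: bool | None = None
    db_flank_left: str | None = None     # flank copies used by the db fixture
    db_flank_right: str | None = None


def _rand_seq(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _rand_motif(rng, k: int, gc: float) -> str:
    from .ssr import _is_primitive
    while True:
        m = _rand_seq(rng, k, gc)
        if _is_primitive(m):
            return m


def _reps_range(k: int, need_range: bool = False) -> tuple[int, int]:
    lo = DEFAULT_MINIMA[k]
    hi = max(lo, 30 // k)   # cap spans at ~30 bp so products stay designable
    if need_range and hi == lo:
        hi = lo + 1         # divergent pairs need two distinct counts
    return lo, hi


def _plant_ssr(rng, cfg: SimulationConfig, divergent: bool):
    """One SSR contig (flanks + repeat run [+ divergent-copy repeat count]).

    Returns (contig_seq_a, contig_seq_b_or_None, left_len, motif, reps_a,
    reps_b); the contig is regenerated until the miner sees exactly the
    planted locus and nothing else, so flanks are guaranteed SSR-free.
    """
    ks = sorted(cfg.motif_weights)
    w = np.array([cfg.motif_weights[k] for k in ks], dtype=float)
    w /= w.sum()
    for _attempt in range(300):
        k = int(rng.choice(np.array(ks), p=w))
        lo, hi = _reps_range(k, need_range=divergent)
        reps_a = int(rng.integers(lo, hi + 1))
        reps_b = reps_a
        if divergent:
            while reps_b == reps_a:
                reps_b = int(rng.integers(lo, hi + 1))
        motif = _rand_motif(rng, k, cfg.gc_target)
        left = _rand_seq(rng, int(rng.integers(120, 201)), cfg.gc_target)
        right = _rand_seq(rng, int(rng.integers(120, 201)), cfg.gc_target)
        seq_a = left + motif * reps_a + right
        found = find_ssrs(seq_a)
        if not (len(found) == 1 and found[0].start == len(left) + 1
                and found[0].end == len(left) + k * reps_a
                and found[0].motif == motif):
            continue
        seq_b = None
        if divergent:
            seq_b = left + motif * reps_b + right
            found_b = find_ssrs(seq_b)
            if not (len(found_b) == 1 and found_b[0].start == len(left) + 1
                    and found_b[0].end == len(left) + k * reps_b
                    and found_b[0].motif == motif):
                continue
        return seq_a, seq_b, len(left), motif, reps_a, reps_b
    raise RuntimeError("infeasible packing: could not plant a clean SSR contig")


def _plant_variant_contig(rng, cfg: SimulationConfig, indel_len: int = 0,
                          ins_in_a: bool = True):
    """An ancestral contig pair differing at one planted site.

    indel_len == 0 -> SNP; otherwise one parent carries ``indel_len`` extra
    bases.  Returns (seq_a, seq_b, anchor_pos0, a_allele_info) where the
    allele strings follow the anchored (VCF-like) convention.
    """
    for _attempt in range(300):
        L = int(rng.integers(max(320, cfg.contig_len_min + 120),
                             cfg.contig_len_max + 1))
        anc = _rand_seq(rng, L, cfg.gc_target)
        ap = int(rng.integers(140, L - 140))
        if indel_len == 0:
            base_b = anc[ap]
            if rng.random() < cfg.tstv_target / (1.0 + cfg.tstv_target):
                base_a = _TS_PARTNER[base_b]
            else:
                base_a = _TV_PARTNERS[base_b][int(rng.integers(0, 2))]
            seq_a = anc[:ap] + base_a + anc[ap + 1:]
            seq_b = anc
            if find_ssrs(seq_a) or find_ssrs(seq_b):
                continue
            return seq_a, seq_b, ap, (base_a, base_b)
        long_seq = anc
        short_seq = anc[:ap] + anc[ap + indel_len:]
        anchor = anc[ap - 1]
        inserted = anc[ap:ap + indel_len]
        if ins_in_a:
            seq_a, seq_b = long_seq, short_seq
        else:
            seq_a, seq_b = short_seq, long_seq
        if find_ssrs(seq_a) or find_ssrs(seq_b):
            continue
        return seq_a, seq_b, ap, (anchor, inserted)
    raise RuntimeError("infeasible packing: could not plant a clean variant contig")


def _noise_plan(rng, n: int, fractions: list[tuple[str, float]]) -> list[str]:
    """Assign each of n items a mutually exclusive noise label (or 'clean')."""
    labels = ["clean"] * n
    order = np.arange(n)
    rng.shuffle(order)
    cursor = 0
    for label, frac in fractions:
        count = int(round(frac * n))
        for i in range(count):
            if cursor >= n:
                break
            labels[order[cursor]] = label
            cursor += 1
    return labels


def generate_parents(config: SimulationConfig):
    """Generate the two parental contig sets and the truth table.

    Deterministic for a fixed seed.  Divergent SSRs differ only in repeat
    count inside identical flanks; parent-only SSRs sit on contigs present in
    one parent; variant contig pairs differ at exactly the planted site.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    contigs_a: list[Contig] = []
    contigs_b: list[Contig] = []
    truth: list[TruthRow] = []

    def add_ssr(kind: str, fid: str, divergent: bool, in_a: bool, in_b: bool):
        seq_a, seq_b, left_len, motif, reps_a, reps_b = _plant_ssr(
            rng, config, divergent)
        if seq_b is None:
            seq_b = seq_a
        k = len(motif)
        row = TruthRow(
            feature_id=fid, kind=kind,
            motif=motif, canonical_class=canonical_motif(motif),
            db_flank_left=seq_a[left_len - 100:left_len],
        )
        if in_a:
            cid = f"A_{fid}"
            contigs_a.append(Contig(cid, seq_a, "A"))
            row.contig_a = cid
            row.start_a, row.end_a = left_len + 1, left_len + k * reps_a
            row.reps_a = reps_a
            row.db_flank_right = seq_a[left_len + k * reps_a:
                                       left_len + k * reps_a + 100]
        if in_b:
            cid = f"B_{fid}"
            contigs_b.append(Contig(cid, seq_b, "B"))
            row.contig_b = cid
            row.start_b, row.end_b = left_len + 1, left_len + k * reps_b
            row.reps_b = reps_b
            if not in_a:
                row.db_flank_right = seq_b[left_len + k * reps_b:
                                           left_len + k * reps_b + 100]
        row.expected_status = ("SHARED" if in_a and in_b
                               else "A_ONLY" if in_a else "B_ONLY")
        row.expected_poly = bool(divergent)
        if kind != "ssr_shared_equal":
            row.expected_redundant = False   # db fixture may flip this
        truth.append(row)

    for i in range(config.n_ssr_shared_equal):
        add_ssr("ssr_shared_equal", f"sse{i:04d}", False, True, True)
    for i in range(config.n_ssr_shared_divergent):
        add_ssr("ssr_divergent", f"ssd{i:04d}", True, True, True)
    for i in range(config.n_ssr_a_only):
        add_ssr("ssr_a_only", f"ssa{i:04d}", False, True, False)
    for i in range(config.n_ssr_b_only):
        add_ssr("ssr_b_only", f"ssb{i:04d}", False, False, True)

    zyg_plan_snp = _noise_plan(rng, config.n_snp, [
        ("HET", config.frac_het), ("UNKNOWN", config.frac_unknown)])
    filt_plan_snp = _noise_plan(rng, config.n_snp, [
        ("low_depth", config.frac_snp_low_depth)])
    for i in range(config.n_snp):
        seq_a, seq_b, ap, (base_a, base_b) = _plant_variant_contig(rng, config)
        fid = f"snp{i:04d}"
        cid_a, cid_b = f"A_{fid}", f"B_{fid}"
        contigs_a.append(Contig(cid_a, seq_a, "A"))
        contigs_b.append(Contig(cid_b, seq_b, "B"))
        zyg = zyg_plan_snp[i] if zyg_plan_snp[i] != "clean" else "HOM"
        removed = filt_plan_snp[i] == "low_depth"
        row = TruthRow(
            feature_id=fid, kind="snp", contig_a=cid_a, contig_b=cid_b,
            start_a=ap + 1, end_a=ap + 1, start_b=ap + 1, end_b=ap + 1,
            pos_ab=ap + 1, ref_ab=base_b, alt_ab=base_a,
            pos_ba=ap + 1, ref_ba=base_a, alt_ba=base_b,
            zyg=zyg,
            filter_ab="REMOVE:DP<min_depth" if removed else "KEEP",
            filter_ba="KEEP",
            expected_status="B_ONLY" if removed else "SHARED",
            expected_poly=bool(not removed and zyg == "HOM"
                               and base_a != base_b),
        )
        truth.append(row)

    zyg_plan_ind = _noise_plan(rng, config.n_indel, [
        ("HET", config.frac_het), ("UNKNOWN", config.frac_unknown)])
    filt_plan_ind = _noise_plan(rng, config.n_indel, [
        ("fail_mq0", config.frac_indel_fail_mq0),
        ("fail_mq", config.frac_indel_fail_mq),
        ("fail_qual", config.frac_indel_fail_qual),
        ("fail_dp", config.frac_indel_fail_dp)])
    fail_reason = {"fail_mq0": "MQ0>=4&MQ0/DP>0.1", "fail_mq": "MQ<30",
                   "fail_qual": "QUAL<50", "fail_dp": "DP<5"}
    p_geom = 1.0 / config.indel_mean_len
    for i in range(config.n_indel):
        ilen = int(min(rng.geometric(p_geom), 8))
        ins_in_a = bool(rng.integers(0, 2))
        seq_a, seq_b, ap, (anchor, inserted) = _plant_variant_contig(
            rng, config, indel_len=ilen, ins_in_a=ins_in_a)
        fid = f"ind{i:04d}"
        cid_a, cid_b = f"A_{fid}", f"B_{fid}"
        contigs_a.append(Contig(cid_a, seq_a, "A"))
        contigs_b.append(Contig(cid_b, seq_b, "B"))
        zyg = zyg_plan_ind[i] if zyg_plan_ind[i] != "clean" else "HOM"
        plan = filt_plan_ind[i]
        removed = plan != "clean"
        if ins_in_a:
            # A carries the insertion; in the A-vs-B table (on B's contig)
            # the site is an INS, reciprocally a DEL on A's contig
            rec_ab = (ap, anchor, anchor + inserted)
            rec_ba = (ap, anchor + inserted, anchor)
            span_a = (ap, ap + ilen)
            span_b = (ap, ap)
        else:
            rec_ab = (ap, anchor + inserted, anchor)
            rec_ba = (ap, anchor, anchor + inserted)
            span_a = (ap, ap)
            span_b = (ap, ap + ilen)
        row = TruthRow(
            feature_id=fid, kind="indel", contig_a=cid_a, contig_b=cid_b,
            start_a=span_a[0], end_a=span_a[1],
            start_b=span_b[0], end_b=span_b[1],
            pos_ab=rec_ab[0], ref_ab=rec_ab[1], alt_ab=rec_ab[2],
            pos_ba=rec_ba[0], ref_ba=rec_ba[1], alt_ba=rec_ba[2],
            zyg=zyg,
            filter_ab=f"REMOVE:{fail_reason[plan]}" if removed else "KEEP",
            filter_ba="KEEP",
            expected_status="B_ONLY" if removed else "SHARED",
            expected_poly=bool(not removed and zyg == "HOM"),
        )
        truth.append(row)

    for i in range(config.n_background):
        for _attempt in range(300):
            L = int(rng.integers(config.contig_len_min, config.contig_len_max + 1))
            seq = _rand_seq(rng, L, config.gc_target)
            if not find_ssrs(seq):
                break
        else:
            raise RuntimeError("could not draw an SSR-free background contig")
        contigs_a.append(Contig(f"A_bg{i:03d}", seq, "A"))
    for i in range(config.n_background):
        for _attempt in range(300):
            L = int(rng.integers(config.contig_len_min, config.contig_len_max + 1))
            seq = _rand_seq(rng, L, config.gc_target)
            if not find_ssrs(seq):
                break
        else:
            raise RuntimeError("could not draw an SSR-free background contig")
        contigs_b.append(Contig(f"B_bg{i:03d}", seq, "B"))

    return contigs_a, contigs_b, truth


def _depth(rng, cfg, floor: int = 10) -> int:
    return max(int(rng.poisson(cfg.depth_mean)), floor)


def _allele_depths(rng, dp: int, zyg: str) -> tuple[int, int]:
    """(ad_ref, ad_alt) consistent with the planted zygosity; the sampled
    parent is homozygous for the ALT allele at a HOM site."""
    if zyg == "HOM":
        m_max = int(np.floor(0.0999 * dp))
        minor = int(rng.integers(0, m_max + 1))
        return minor, dp - minor
    if zyg == "HET":
        while True:
            alt = int(rng.binomial(dp, 0.5))
            if 0 < alt < dp and min(alt, dp - alt) / dp > 0.25:
                return dp - alt, alt
    # grey zone: MAF strictly inside (0.10, 0.25)
    while True:
        minor = int(round(dp * rng.uniform(0.12, 0.23)))
        if 0.10 < minor / dp < 0.25:
            return minor, dp - minor


def emit_variant_calls(truth, config: SimulationConfig):
    """Caller-style reciprocal variant tables for the planted sites.

    Metrics are drawn so every record passes the hard filters unless its
    truth row plans a specific clause failure, and allele depths match the
    planted zygosity.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng([config.seed, 2])
    recs_ab: list[VariantRecord] = []
    recs_ba: list[VariantRecord] = []

    def build(contig_id, pos, ref, alt, zyg, plan):
        dp = _depth(rng, config)
        mq, mq0, qual = 60.0, 0, 200.0
        if plan == "REMOVE:DP<5":
            dp = 4
        elif plan == "REMOVE:DP<min_depth":
            dp = int(rng.integers(1, 8))
        elif plan == "REMOVE:MQ<30":
            mq = 25.0
        elif plan == "REMOVE:QUAL<50":
            qual = 30.0
        elif plan == "REMOVE:MQ0>=4&MQ0/DP>0.1":
            mq0 = max(4, int(0.15 * dp) + 1)
        ad_ref, ad_alt = _allele_depths(rng, dp, zyg)
        return VariantRecord(contig_id=contig_id, pos=pos, ref=ref, alt=alt,
                             DP=dp, MQ=mq, MQ0=mq0, QUAL=qual,
                             ad_ref=ad_ref, ad_alt=ad_alt)

    for row in truth:
        if row.kind not in ("snp", "indel"):
            continue
        if row.contig_b is not None and row.pos_ab is not None:
            recs_ab.append(build(row.contig_b, row.pos_ab, row.ref_ab,
                                 row.alt_ab, row.zyg, row.filter_ab))
        if row.contig_a is not None and row.pos_ba is not None:
            recs_ba.append(build(row.contig_a, row.pos_ba, row.ref_ba,
                                 row.alt_ba, row.zyg, row.filter_ba))
    return recs_ab, recs_ba


def known_db_fixture(truth, overlap_fraction: float = 0.5, seed: int = 0,
                     n_extra: int = 20, gc: float = 0.34) -> KnownMarkerDB:
    """A known-marker database overlapping a chosen fraction of candidates.

    For the designated fraction of candidate-destined SSR rows the record is
    an exact copy of the 100 bp flanks either side of the SSR (SSR excised),
    guaranteeing >= 50 matched non-SSR bases; the rest of the database is
    unrelated random sequence.  Marks ``expected_redundant`` on the truth rows.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    eligible = [r for r in truth
                if r.kind in ("ssr_divergent", "ssr_a_only", "ssr_b_only")]
    k = int(round(overlap_fraction * len(eligible)))
    chosen_idx = set(
        rng.choice(len(eligible), size=k, replace=False).tolist()) if k else set()
    records: dict[str, str] = {}
    for i, row in enumerate(eligible):
        row.expected_redundant = i in chosen_idx
        if i in chosen_idx:
            records[f"KM_{row.feature_id}"] = row.db_flank_left + row.db_flank_right
    for i in range(n_extra):
        records[f"KMX{i:03d}"] = _rand_seq(rng, 300, gc)
    return KnownMarkerDB(records)


TRUTH_COLUMNS = list(TruthRow.__dataclass_fields__)


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for row in truth:
            d = asdict(row)
            fh.write("\t".join("" if d[c] is None else str(d[c])
                               for c in TRUTH_COLUMNS) + "\n")


def evaluate_recovery(result, truth) -> dict:
    """Compare a pipeline run against the truth table, check by check.

    Checks anchoring status and polymorphism flag of every planted SSR,
    filter decision and zygosity of every emitted variant record, shared-site
    classification, and the redundancy flag of every candidate the db fixture
    designated.  Returns totals, the recovery percentage, and mismatches.
    """
    checks = 0
    mismatches: list[str] = []

    def expect(cond, label):
        nonlocal checks
        checks += 1
        if not cond:
            mismatches.append(label)

    ssr_status = {}
    for st in result.ssr_partition.statuses_a.values():
        ssr_status[st.marker_id] = st
    for st in result.ssr_partition.statuses_b.values():
        ssr_status[st.marker_id] = st
    var_status = {}
    for st in result.variant_partition.statuses_a.values():
        var_status[st.marker_id] = st
    for st in result.variant_partition.statuses_b.values():
        var_status[st.marker_id] = st

    for row in truth:
        if row.kind.startswith("ssr"):
            mid_a = (f"A:{row.contig_a}:{row.start_a}-{row.end_a}"
                     if row.contig_a else None)
            mid_b = (f"B:{row.contig_b}:{row.start_b}-{row.end_b}"
                     if row.contig_b else None)
            if row.expected_status == "SHARED":
                st = ssr_status.get(mid_a)
                expect(st is not None and st.status == "SHARED",
                       f"{row.feature_id}: expected SHARED, got "
                       f"{getattr(st, 'status', 'missing')}")
                expect(st is not None
                       and st.insilico_polymorphic == row.expected_poly,
                       f"{row.feature_id}: polymorphism flag mismatch")
                stb = ssr_status.get(mid_b)
                expect(stb is not None and stb.status == "SHARED",
                       f"{row.feature_id}: B member not SHARED")
            elif row.expected_status == "A_ONLY":
                st = ssr_status.get(mid_a)
                expect(st is not None and st.status == "A_ONLY",
                       f"{row.feature_id}: expected A_ONLY, got "
                       f"{getattr(st, 'status', 'missing')}")
            else:
                st = ssr_status.get(mid_b)
                expect(st is not None and st.status == "B_ONLY",
                       f"{row.feature_id}: expected B_ONLY, got "
                       f"{getattr(st, 'status', 'missing')}")
            if row.expected_redundant is not None:
                if row.kind == "ssr_b_only":
                    mid = mid_b
                else:
                    mid = mid_a
                got = result.redundancy.get(mid)
                expect(got == row.expected_redundant,
                       f"{row.feature_id}: redundancy {got} != "
                       f"{row.expected_redundant}")
        else:
            key_ab = ("AB", row.contig_b, row.pos_ab)
            key_ba = ("BA", row.contig_a, row.pos_ba)
            expect(result.filter_map.get(key_ab) == row.filter_ab,
                   f"{row.feature_id}: AB filter "
                   f"{result.filter_map.get(key_ab)} != {row.filter_ab}")
            expect(result.filter_map.get(key_ba) == row.filter_ba,
                   f"{row.feature_id}: BA filter "
                   f"{result.filter_map.get(key_ba)} != {row.filter_ba}")
            if row.filter_ab == "KEEP":
                z = result.zygosity_map.get(key_ab)
                expect(z is not None and z.call == row.zyg,
                       f"{row.feature_id}: AB zygosity "
                       f"{getattr(z, 'call', None)} != {row.zyg}")
            if row.filter_ba == "KEEP":
                z = result.zygosity_map.get(key_ba)
                expect(z is not None and z.call == row.zyg,
                       f"{row.feature_id}: BA zygosity "
                       f"{getattr(z, 'call', None)} != {row.zyg}")
            mid_ab = f"AB:{row.contig_b}:{row.pos_ab}"
            mid_ba = f"BA:{row.contig_a}:{row.pos_ba}"
            if row.expected_status == "SHARED":
                st = var_status.get(mid_ab)
                expect(st is not None and st.status == "SHARED",
                       f"{row.feature_id}: expected SHARED site, got "
                       f"{getattr(st, 'status', 'missing')}")
                expect(st is not None
                       and st.insilico_polymorphic == row.expected_poly,
                       f"{row.feature_id}: site polymorphism flag mismatch")
            elif row.expected_status == "B_ONLY":
                # the AB-direction record was filtered out; the reciprocal
                # record remains and must be direction-specific
                st = var_status.get(mid_ba)
                expect(st is not None and st.status == "B_ONLY",
                       f"{row.feature_id}: expected one-sided site, got "
                       f"{getattr(st, 'status', 'missing')}")
    n_ok = checks - len(mismatches)
    return {
        "n_checks": checks,
        "n_correct": n_ok,
        "recovery_pct": 100.0 * n_ok / checks if checks else 100.0,
        "mismatches": mismatches,
    }
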