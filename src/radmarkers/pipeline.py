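"""End-to-end orchestration of the marker-development workflow.

Stage order: SSR mining per parent -> flank extraction -> cross-parent
anchoring/partition -> variant hard-filtering and zygosity -> shared-site
classification -> redundancy screening of SSR candidates against the known
marker database -> primer-region clustering and primer design -> summary
statistics and the deterministic report.  Partition count identities are
self-checked before the report is written.

Variant sites come in two reciprocal directions: "AB" records (parent A's
reads called against parent B's contigs, so each site lives on a B contig and
its ALT allele is parent A's allele) and "BA" records (the converse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import variants as vr
from .compare import (classify_ssr_pair, classify_variant_pair,
                      extract_flanks, partition_markers)
from .io import PipelineConfig, write_marker_report
from .primers import cluster_markers, design_primers
from .redundancy import KnownMarkerDB, is_redundant, mask_ssr
from .ssr import find_ssrs, ssr_summary
from .stats import marker_frequency, verify_partition_counts

log = logging.getLogger("radmarkers")


@dataclass
class PipelineResult:
    config: PipelineConfig
    ssr_a: list = field(default_factory=list)
    ssr_b: list = field(default_factory=list)
    ssr_partition: object = None
    variant_partition: object = None
    filter_rows: list = field(default_factory=list)
    filter_map: dict = field(default_factory=dict)     # (dir, contig, pos) -> str
    zygosity_map: dict = field(default_factory=dict)   # (dir, contig, pos) -> call
    redundancy: dict = field(default_factory=dict)     # marker_id -> bool
    redundancy_hits: dict = field(default_factory=dict)
    primer_rows: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)
    report_rows: list = field(default_factory=list)

    def write_report(self, path) -> None:
        write_marker_report(self.report_rows, self.stats, path)


def _flank_set(markers, contig_map, genotype, cfg, id_fn):
    flanked, unanchorable = [], []
    for m in markers:
        fm = extract_flanks(m, contig_map, cfg.flank_min, cfg.flank_max,
                            genotype=genotype, marker_id=id_fn(m))
        if fm is None:
            unanchorable.append(id_fn(m))
        else:
            flanked.append(fm)
    return flanked, unanchorable


def _screen_variants(records, direction, cfg, result):
    """Hard-filter one direction's records; returns kept records with calls."""
    kept = []
    for rec in records:
        if rec.vtype == "SNP":
            dec = vr.snp_depth_filter(rec, cfg.snp_min_depth)
        else:
            dec = vr.indel_hard_filter(rec)
        key = (direction, rec.contig_id, rec.pos)
        result.filter_map[key] = (
            "KEEP" if dec.keep else f"REMOVE:{dec.reason}")
        row = {"direction": direction, "contig": rec.contig_id, "pos": rec.pos,
               "vtype": rec.vtype,
               "decision": "KEEP" if dec.keep else "REMOVE",
               "reason": dec.reason or "", "maf": "", "call": ""}
        if dec.keep:
            if rec.ad_ref + rec.ad_alt > 0:
                call = vr.zygosity(rec, cfg.maf_hom, cfg.maf_het)
            else:
                call = vr.ZygosityCall(rec.contig_id, rec.pos, float("nan"),
                                       vr.UNKNOWN)
            result.zygosity_map[key] = call
            row["maf"] = round(call.maf, 4)
            row["call"] = call.call
            kept.append(rec)
        result.filter_rows.append(row)
    return kept


def run_pipeline(config: PipelineConfig, contigs_a, contigs_b,
                 variants_ab=(), variants_ba=(),
                 known_db: KnownMarkerDB | None = None) -> PipelineResult:
    """Run every stage on in-memory inputs; deterministic given the config."""
    config.validate()
    result = PipelineResult(config=config)
    map_a = {c.id: c for c in contigs_a}
    map_b = {c.id: c for c in contigs_b}
    if len(map_a) != len(list(contigs_a)) or len(map_b) != len(list(contigs_b)):
        raise ValueError("duplicate contig ids within a genotype")

    # --- SSR mining ---------------------------------------------------------
    for c in contigs_a:
        result.ssr_a.extend(find_ssrs(c, config.ssr_minima, config.compound_gap))
    for c in contigs_b:
        result.ssr_b.extend(find_ssrs(c, config.ssr_minima, config.compound_gap))
    log.info("mined %d SSRs in A, %d in B", len(result.ssr_a), len(result.ssr_b))

    # --- SSR anchoring ------------------------------------------------------
    ssr_id = lambda g: (lambda m: f"{g}:{m.contig_id}:{m.start}-{m.end}")
    fa, ua = _flank_set(result.ssr_a, map_a, "A", config, ssr_id("A"))
    fb, ub = _flank_set(result.ssr_b, map_b, "B", config, ssr_id("B"))
    result.ssr_partition = partition_markers(
        fa, fb, ua, ub, config.anchor_evalue, config.geometry_window,
        classify_pair=classify_ssr_pair)
    verify_partition_counts(result.ssr_partition.counts,
                            len(fa) + len(ua), len(fb) + len(ub))
    log.info("SSR partition: %s", result.ssr_partition.counts)
    flank_by_id = {m.marker_id: m for m in fa + fb}

    # --- variant screening and anchoring ------------------------------------
    kept_ab = _screen_variants(variants_ab, "AB", config, result)
    kept_ba = _screen_variants(variants_ba, "BA", config, result)
    var_id = lambda d: (lambda r: f"{d}:{r.contig_id}:{r.pos}")
    fva, uva = _flank_set(kept_ab, map_b, "AB", config, var_id("AB"))
    fvb, uvb = _flank_set(kept_ba, map_a, "BA", config, var_id("BA"))

    def classify_sites(rec_ab, rec_ba):
        za = result.zygosity_map[("AB", rec_ab.contig_id, rec_ab.pos)]
        zb = result.zygosity_map[("BA", rec_ba.contig_id, rec_ba.pos)]
        return classify_variant_pair(rec_ab, rec_ba, za, zb)

    result.variant_partition = partition_markers(
        fva, fvb, uva, uvb, config.anchor_evalue, config.geometry_window,
        classify_pair=classify_sites)
    verify_partition_counts(result.variant_partition.counts,
                            len(fva) + len(uva), len(fvb) + len(uvb))
    log.info("variant partition: %s", result.variant_partition.counts)
    flank_by_id.update({m.marker_id: m for m in fva + fvb})

    # --- redundancy screening of SSR candidates -----------------------------
    # anchoring precedes primer design here, so the known-marker comparison
    # uses the marker's flank region (flanks + masked SSR) as the
    # inter-primer proxy; masking removes the repeat itself either way
    for mid in result.ssr_partition.candidates:
        fm = flank_by_id[mid]
        locus = fm.payload
        contig = (map_a if fm.genotype == "A" else map_b)[fm.contig_id]
        region = (fm.left_flank
                  + contig.sequence[locus.start - 1:locus.end]
                  + fm.right_flank)
        span = (len(fm.left_flank) + 1, len(fm.left_flank) + locus.span_len)
        masked = mask_ssr(region, [span])
        if known_db is None:
            result.redundancy[mid] = False
            result.redundancy_hits[mid] = None
        else:
            red, hit = is_redundant(masked, known_db,
                                    config.redundancy_matched_min,
                                    config.redundancy_evalue)
            result.redundancy[mid] = red
            result.redundancy_hits[mid] = hit

    # --- primer regions -----------------------------------------------------
    novel_ssr = [m for m in result.ssr_partition.candidates
                 if not result.redundancy[m]]
    all_candidates = novel_ssr + list(result.variant_partition.candidates)
    by_contig: dict[tuple, list] = {}
    for mid in all_candidates:
        fm = flank_by_id[mid]
        src = "A" if fm.genotype in ("A", "BA") else "B"
        by_contig.setdefault((src, fm.contig_id), []).append(
            (mid, fm.start, fm.end))
    n_designed = n_failed = 0
    for (src, cid) in sorted(by_contig):
        contig = (map_a if src == "A" else map_b)[cid]
        for region in cluster_markers(by_contig[(src, cid)],
                                      config.cluster_dist,
                                      config.primer.clustered_product_max,
                                      config.primer.len_min, contig_id=cid):
            pair = design_primers(region, contig, config.primer)
            row = {"contig": cid, "genotype": src,
                   "markers": ";".join(sorted(region.member_ids)),
                   "span_start": region.span_start,
                   "span_end": region.span_end,
                   "clustered": region.clustered}
            if pair is None:
                row.update({"status": "FAILED", "reason": "no_valid_pair"})
                n_failed += 1
            else:
                row.update({
                    "status": "OK", "reason": "",
                    "left_seq": pair.left_seq, "right_seq": pair.right_seq,
                    "left_pos": pair.left_pos, "right_pos": pair.right_pos,
                    "tm_left": round(pair.tm_left, 2),
                    "tm_right": round(pair.tm_right, 2),
                    "gc_left": round(pair.gc_left, 2),
                    "gc_right": round(pair.gc_right, 2),
                    "product_size": pair.product_size})
                n_designed += 1
            result.primer_rows.append(row)

    # --- statistics and report ----------------------------------------------
    kb_a = sum(c.length for c in contigs_a) / 1000.0
    kb_b = sum(c.length for c in contigs_b) / 1000.0
    sum_a = ssr_summary(result.ssr_a, kb_a) if result.ssr_a else None
    sum_b = ssr_summary(result.ssr_b, kb_b) if result.ssr_b else None
    kept_snps = [r for r in kept_ab + kept_ba if r.vtype == "SNP"]
    tstv = vr.tstv_ratio(kept_snps)
    sp, vp = result.ssr_partition.counts, result.variant_partition.counts
    result.stats = {
        "ssr_total_A": len(result.ssr_a),
        "ssr_total_B": len(result.ssr_b),
        "ssr_frequency_A": sum_a.frequency_label if sum_a else "NA",
        "ssr_frequency_B": sum_b.frequency_label if sum_b else "NA",
        "ssr_shared": sp["shared"],
        "ssr_insilico_poly": sp["insilico_poly"],
        "ssr_a_only": sp["a_only"],
        "ssr_b_only": sp["b_only"],
        "ssr_unanchorable": sp["unanchorable"],
        "ssr_candidates": sp["candidates"],
        "ssr_redundant": sum(1 for v in result.redundancy.values() if v),
        "variant_shared": vp["shared"],
        "variant_insilico_poly": vp["insilico_poly"],
        "variant_ab_only": vp["a_only"],
        "variant_ba_only": vp["b_only"],
        "variant_candidates": vp["candidates"],
        "variants_removed": sum(1 for r in result.filter_rows
                                if r["decision"] == "REMOVE"),
        "tstv": "NA" if tstv is None else round(tstv, 2),
        "primer_pairs_designed": n_designed,
        "primer_design_failures": n_failed,
        "total_kb_A": round(kb_a, 2),
        "total_kb_B": round(kb_b, 2),
    }
    if result.ssr_a:
        result.stats["ssr_marker_frequency_kb_A"] = marker_frequency(
            len(result.ssr_a), kb_a)
    if result.ssr_b:
        result.stats["ssr_marker_frequency_kb_B"] = marker_frequency(
            len(result.ssr_b), kb_b)

    primer_status = {}
    for row in result.primer_rows:
        for mid in row["markers"].split(";"):
            primer_status[mid] = row["status"]
    for part in (result.ssr_partition, result.variant_partition):
        for statuses in (part.statuses_a, part.statuses_b):
            for st in statuses.values():
                fm = flank_by_id.get(st.marker_id)
                genotype, contig, start, end, kind = "", "", 0, 0, ""
                if fm is not None:
                    genotype, contig = fm.genotype, fm.contig_id
                    start, end, kind = fm.start, fm.end, fm.kind
                else:
                    parts = st.marker_id.split(":")
                    if len(parts) == 3:
                        genotype, contig = parts[0], parts[1]
                        span = parts[2].split("-")
                        start = int(span[0])
                        end = int(span[-1])
                result.report_rows.append({
                    "marker_id": st.marker_id, "genotype": genotype,
                    "kind": kind, "contig": contig,
                    "start": start, "end": end, "status": st.status,
                    "partner": st.partner_id or "",
                    "insilico_polymorphic": st.insilico_polymorphic,
                    "redundant": result.redundancy.get(st.marker_id, ""),
                    "primer_status": primer_status.get(st.marker_id, ""),
                })
    return result


def run_from_paths(config, fasta_a, fasta_b, table_ab=None, table_ba=None,
                   db_fasta=None, report_path=None) -> PipelineResult:
    """Convenience wrapper reading every input from disk."""
    from .io import read_fasta, read_variant_table
    contigs_a = read_fasta(fasta_a, genotype="A")
    contigs_b = read_fasta(fasta_b, genotype="B")
    v_ab = read_variant_table(table_ab) if table_ab else []
    v_ba = read_variant_table(table_ba) if table_ba else []
    db = KnownMarkerDB.from_fasta(db_fasta) if db_fasta else None
    result = run_pipeline(config, contigs_a, contigs_b, v_ab, v_ba, db)
    if report_path:
        result.write_report(report_path)
    return result
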