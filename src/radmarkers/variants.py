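"""Hard filters and zygosity calls for caller-style variant records.

InDel records are removed when any one of four clauses holds:
(MQ0 >= 4 AND MQ0/DP > 0.1), MQ < 30, QUAL < 50, or DP < 5 — the standard
hard-filter idiom, with the bracketed MQ0 ratio read as a conjunction with
the MQ0 count.  SNPs are kept at coverage depth >= 8.  Site zygosity is
called from the minor-allele frequency (MAF) of the two allele depths:
homozygous below 0.10, heterozygous above 0.25, unknown in between
(boundaries inclusive to unknown, per the strict "below"/"above" wording).
"""

from __future__ import annotations

from dataclasses import dataclass

# removal reasons, in clause evaluation order
REASON_MQ0 = "MQ0>=4&MQ0/DP>0.1"
REASON_MQ = "MQ<30"
REASON_QUAL = "QUAL<50"
REASON_DP = "DP<5"
REASON_LOW_DEPTH = "DP<min_depth"

HOM, HET, UNKNOWN = "HOM", "HET", "UNKNOWN"


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.keep


KEEP = FilterDecision(True, None)


def indel_hard_filter(record) -> FilterDecision:
    """Apply the four-clause InDel removal rule; reason = first failing clause."""
    if record.vtype not in ("INS", "DEL"):
        raise ValueError(f"indel_hard_filter expects INS/DEL, got {record.vtype}")
    if record.DP == 0:
        # depth clause short-circuits so the MQ0/DP ratio is never evaluated
        return FilterDecision(False, REASON_DP)
    if record.MQ0 >= 4 and record.MQ0 / (1.0 * record.DP) > 0.1:
        return FilterDecision(False, REASON_MQ0)
    if record.MQ < 30.0:
        return FilterDecision(False, REASON_MQ)
    if record.QUAL < 50:
        return FilterDecision(False, REASON_QUAL)
    if record.DP < 5:
        return FilterDecision(False, REASON_DP)
    return KEEP


def snp_depth_filter(record, min_depth: int = 8) -> FilterDecision:
    """Keep a SNP iff its coverage depth reaches ``min_depth`` (inclusive)."""
    if record.vtype != "SNP":
        raise ValueError(f"snp_depth_filter expects SNP, got {record.vtype}")
    if record.DP >= min_depth:
        return KEEP
    return FilterDecision(False, REASON_LOW_DEPTH)


@dataclass(frozen=True)
class ZygosityCall:
    contig_id: str
    pos: int
    maf: float
    call: str


def zygosity(record, hom_thr: float = 0.10, het_thr: float = 0.25) -> ZygosityCall:
    """Call a site HOM/HET/UNKNOWN from its minor-allele frequency."""
    total = record.ad_ref + record.ad_alt
    if total <= 0:
        raise ValueError(
            f"{record.contig_id}:{record.pos}: zero allele depth sum"
        )
    maf = min(record.ad_ref, record.ad_alt) / total
    if maf < hom_thr:
        call = HOM
    elif maf > het_thr:
        call = HET
    else:
        call = UNKNOWN
    return ZygosityCall(record.contig_id, record.pos, maf, call)


_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


def tstv_ratio(snps) -> float | None:
    """Transition/transversion ratio of SNP records; None when undefined."""
    ts = tv = 0
    for rec in snps:
        if rec.vtype != "SNP":
            continue
        pair = frozenset((rec.ref, rec.alt))
        if pair in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def filter_audit(indels=(), snps=(), *, min_depth: int = 8,
                 hom_thr: float = 0.10, het_thr: float = 0.25) -> list[dict]:
    """Per-site audit rows: decision, reason, MAF and zygosity for kept sites."""
    rows = []
    for rec in indels:
        d = indel_hard_filter(rec)
        row = {"contig": rec.contig_id, "pos": rec.pos, "vtype": rec.vtype,
               "decision": "KEEP" if d.keep else "REMOVE",
               "reason": d.reason or "", "maf": "", "call": ""}
        if d.keep and rec.ad_ref + rec.ad_alt > 0:
            z = zygosity(rec, hom_thr, het_thr)
            row["maf"], row["call"] = round(z.maf, 4), z.call
        rows.append(row)
    for rec in snps:
        d = snp_depth_filter(rec, min_depth)
        row = {"contig": rec.contig_id, "pos": rec.pos, "vtype": rec.vtype,
               "decision": "KEEP" if d.keep else "REMOVE",
               "reason": d.reason or "", "maf": "", "call": ""}
        if d.keep and rec.ad_ref + rec.ad_alt > 0:
            z = zygosity(rec, hom_thr, het_thr)
            row["maf"], row["call"] = round(z.maf, 4), z.call
        rows.append(row)
    return rows
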