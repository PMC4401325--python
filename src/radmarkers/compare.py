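"""Cross-genotype marker anchoring by flanking-sequence alignment.

Two assemblies of the same species share many loci but under different contig
names; a marker found in parent A is declared the *same locus* as a marker in
parent B when the immediate flanking sequences (>= 20 bp on both sides) of
the two markers align with E-value <= 1e-5, in a consistent orientation and
with compatible geometry.  Anchored (SHARED) marker pairs are then classified
as in-silico polymorphic — SSR pairs whose repeat counts differ, or variant
site pairs at which both parents are homozygous for different alleles — and
unanchored markers become parent-specific candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import WORD_SIZE, local_align
from .io import Contig, VariantRecord
from .ssr import SSRLocus

SHARED, A_ONLY, B_ONLY, UNANCHORABLE = "SHARED", "A_ONLY", "B_ONLY", "UNANCHORABLE"


class MarkerInconsistencyError(ValueError):
    """A SHARED pair whose payloads disagree in a way that is not polymorphism."""


@dataclass(frozen=True)
class FlankedMarker:
    """A marker plus its clean (N-free) flanking sequences."""

    marker_id: str
    genotype: str
    kind: str              # SSR | SNP | INDEL
    contig_id: str
    start: int             # 1-based inclusive locus span
    end: int
    left_flank: str
    right_flank: str
    payload: object = None

    @property
    def locus_len(self) -> int:
        return self.end - self.start + 1


@dataclass
class MarkerStatus:
    marker_id: str
    status: str
    partner_id: str | None = None
    insilico_polymorphic: bool = False
    inconsistent: bool = False
    zygosity_pair: tuple | None = None
    n_partners: int = 0


def _marker_span(marker) -> tuple[str, int, int, str]:
    if isinstance(marker, SSRLocus):
        return marker.contig_id, marker.start, marker.end, "SSR"
    if isinstance(marker, VariantRecord):
        s, e = marker.span
        kind = "SNP" if marker.vtype == "SNP" else "INDEL"
        return marker.contig_id, s, e, kind
    raise TypeError(f"cannot flank {type(marker).__name__}")


def extract_flanks(marker, contigs, flank_min: int = 20, flank_max: int = 200,
                   genotype: str = "", marker_id: str | None = None):
    """Extract up to ``flank_max`` clean bases either side of a marker.

    ``contigs`` maps contig id -> Contig.  Returns a FlankedMarker, or None
    when either side offers fewer than ``flank_min`` N-free bases
    (the marker is then unanchorable).  Unknown contig -> KeyError.
    """
    contig_id, start, end, kind = _marker_span(marker)
    if contig_id not in contigs:
        raise KeyError(f"marker references unknown contig {contig_id!r}")
    seq = contigs[contig_id].sequence if isinstance(contigs[contig_id], Contig) \
        else str(contigs[contig_id])
    s0, e0 = start - 1, end  # 0-based half-open locus span
    left = seq[max(0, s0 - flank_max):s0]
    if "N" in left:
        left = left[left.rfind("N") + 1:]
    right = seq[e0:e0 + flank_max]
    if "N" in right:
        right = right[:right.find("N")]
    if len(left) < flank_min or len(right) < flank_min:
        return None
    mid = marker_id or f"{genotype}:{contig_id}:{start}-{end}"
    return FlankedMarker(
        marker_id=mid, genotype=genotype, kind=kind, contig_id=contig_id,
        start=start, end=end, left_flank=left, right_flank=right, payload=marker,
    )


class FlankIndex:
    """Word-indexed flank collection over one genotype's flanked markers."""

    def __init__(self, markers, word_size: int = WORD_SIZE):
        self.markers = {m.marker_id: m for m in markers}
        if len(self.markers) != len(list(markers)):
            raise ValueError("duplicate marker ids")
        seqs = {}
        for m in self.markers.values():
            seqs[(m.marker_id, "L")] = m.left_flank
            seqs[(m.marker_id, "R")] = m.right_flank
        self.word_size = word_size
        self.db_len = sum(len(s) for s in seqs.values())
        self._index: dict[str, set[str]] = {}
        from .align import _words  # shared word enumeration
        for (mid, _side), s in seqs.items():
            for w in _words(s, word_size):
                self._index.setdefault(w, set()).add(mid)

    def candidate_ids(self, fm: FlankedMarker) -> set[str]:
        from .align import _words
        from .ssr import revcomp
        hits: set[str] = set()
        for flank in (fm.left_flank, fm.right_flank):
            for qseq in (flank, revcomp(flank)):
                for w in _words(qseq, self.word_size):
                    if w in self._index:
                        hits |= self._index[w]
        return hits


def _pair_geometry_ok(a: FlankedMarker, b: FlankedMarker, window: int) -> bool:
    # the implied inter-flank gap is the locus span; short InDels shift it a
    # little, paralogous anchors shift it a lot
    return abs(a.locus_len - b.locus_len) <= window


def match_flanks(fm: FlankedMarker, index: FlankIndex, e_cutoff: float = 1e-5,
                 geometry_window: int = 50):
    """Best anchoring partner for ``fm`` among the indexed markers.

    A partner qualifies when BOTH flanks of ``fm`` align to the flanks of the
    same indexed marker at E <= ``e_cutoff``, with a consistent orientation
    (left-left/right-right on '+', left-right/right-left on '-') and
    compatible geometry.  Returns (partner_id or None, n_qualifying_partners).
    """
    hits = []
    for pid in sorted(index.candidate_ids(fm)):
        cand = index.markers[pid]
        if not _pair_geometry_ok(fm, cand, geometry_window):
            continue
        for orientation in ("+", "-"):
            if orientation == "+":
                pairs = ((fm.left_flank, cand.left_flank),
                         (fm.right_flank, cand.right_flank))
            else:
                pairs = ((fm.left_flank, cand.right_flank),
                         (fm.right_flank, cand.left_flank))
            mm = []
            ok = True
            for q, s in pairs:
                m = local_align(q, s, db_len=max(index.db_len, 1),
                                word_size=index.word_size)
                if m is None or m.strand != orientation or m.evalue > e_cutoff:
                    ok = False
                    break
                mm.append(m)
            if ok:
                key = (max(m.evalue for m in mm),
                       -sum(m.identities for m in mm), pid)
                hits.append((key, pid))
                break  # one orientation per partner suffices
    if not hits:
        return None, 0
    hits.sort(key=lambda h: h[0])
    return hits[0][1], len(hits)


def classify_ssr_pair(a: SSRLocus, b: SSRLocus) -> bool:
    """In-silico polymorphism of an anchored SSR pair: repeat counts differ."""
    if a.canonical_class != b.canonical_class:
        raise MarkerInconsistencyError(
            f"anchored SSR pair with different motif classes: "
            f"{a.canonical_class} vs {b.canonical_class}"
        )
    return a.repeats != b.repeats


def classify_variant_pair(a_site, b_site, zyg_a, zyg_b) -> bool:
    """In-silico polymorphism of an anchored site pair: both homozygous for
    different alleles (each direction's alt allele is that parent's allele)."""
    return (zyg_a.call == "HOM" and zyg_b.call == "HOM"
            and a_site.alt != b_site.alt)


@dataclass
class PartitionResult:
    statuses_a: dict = field(default_factory=dict)   # marker_id -> MarkerStatus
    statuses_b: dict = field(default_factory=dict)
    pairs: list = field(default_factory=list)        # (a_id, b_id) SHARED pairs
    counts: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)   # screening set marker ids


def partition_markers(flanked_a, flanked_b, unanchorable_a=(), unanchorable_b=(),
                      e_cutoff: float = 1e-5, geometry_window: int = 50,
                      classify_pair=None) -> PartitionResult:
    """Partition two genotypes' markers into SHARED / A_ONLY / B_ONLY /
    UNANCHORABLE and build the screening candidate list.

    SHARED pairs are mutual best anchors (A->B and B->A agree), which keeps
    anchoring symmetric.  ``classify_pair(payload_a, payload_b)`` returns the
    in-silico polymorphism flag for a SHARED pair (may raise
    MarkerInconsistencyError).  Candidates = in-silico polymorphic pairs
    (represented by the A member) plus parent-specific anchorable markers.
    """
    flanked_a = list(flanked_a)
    flanked_b = list(flanked_b)
    index_a = FlankIndex(flanked_a)
    index_b = FlankIndex(flanked_b)

    best_ab, ambiguous = {}, 0
    for fm in flanked_a:
        partner, n = match_flanks(fm, index_b, e_cutoff, geometry_window)
        if partner is not None:
            best_ab[fm.marker_id] = partner
        if n > 1:
            ambiguous += 1
    best_ba = {}
    for fm in flanked_b:
        partner, n = match_flanks(fm, index_a, e_cutoff, geometry_window)
        if partner is not None:
            best_ba[fm.marker_id] = partner
        if n > 1:
            ambiguous += 1

    res = PartitionResult()
    n_poly = n_inconsistent = 0
    for fm in flanked_a:
        partner = best_ab.get(fm.marker_id)
        if partner is not None and best_ba.get(partner) == fm.marker_id:
            st = MarkerStatus(fm.marker_id, SHARED, partner_id=partner)
            if classify_pair is not None:
                try:
                    st.insilico_polymorphic = bool(classify_pair(
                        fm.payload, index_b.markers[partner].payload))
                except MarkerInconsistencyError:
                    st.inconsistent = True
                if st.insilico_polymorphic:
                    n_poly += 1
                if st.inconsistent:
                    n_inconsistent += 1
            res.statuses_a[fm.marker_id] = st
            res.statuses_b[partner] = MarkerStatus(
                partner, SHARED, partner_id=fm.marker_id,
                insilico_polymorphic=st.insilico_polymorphic,
                inconsistent=st.inconsistent,
            )
            res.pairs.append((fm.marker_id, partner))
            if st.insilico_polymorphic:
                res.candidates.append(fm.marker_id)
        else:
            res.statuses_a[fm.marker_id] = MarkerStatus(fm.marker_id, A_ONLY)
            res.candidates.append(fm.marker_id)
    for fm in flanked_b:
        if fm.marker_id not in res.statuses_b:
            res.statuses_b[fm.marker_id] = MarkerStatus(fm.marker_id, B_ONLY)
            res.candidates.append(fm.marker_id)
    for mid in unanchorable_a:
        res.statuses_a[mid] = MarkerStatus(mid, UNANCHORABLE)
    for mid in unanchorable_b:
        res.statuses_b[mid] = MarkerStatus(mid, UNANCHORABLE)

    shared = len(res.pairs)
    a_only = sum(1 for s in res.statuses_a.values() if s.status == A_ONLY)
    b_only = sum(1 for s in res.statuses_b.values() if s.status == B_ONLY)
    res.counts = {
        "shared": shared,
        "insilico_poly": n_poly,
        "a_only": a_only,
        "b_only": b_only,
        "unanchorable": len(list(unanchorable_a)) + len(list(unanchorable_b)),
        "ambiguous": ambiguous,
        "inconsistent": n_inconsistent,
        "candidates": len(res.candidates),
    }
    return res
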