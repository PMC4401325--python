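"""Marker-region clustering and deterministic primer-pair selection.

Markers lying within 500 bp of each other on one contig share a single
primer region (one pair amplifies them all), with the predicted product kept
under 800 bp for such clustered regions; singleton products stay in the
100-500 bp range.  Primers are 18-24 nt (optimum 20), GC 40-60%, annealing
optimum 57 C, scored by closeness to the optima and picked deterministically
(lowest score, then leftmost, then smallest product).  Melting temperature
uses the basic Wallace-Marmur-style formula Tm = 64.9 + 41*(GC - 16.4)/len.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PrimerConstraints
from .ssr import revcomp


@dataclass(frozen=True)
class PrimerPair:
    left_seq: str
    right_seq: str          # as synthesized: reverse complement of the contig
    left_pos: int           # 1-based start of the left primer site
    right_pos: int          # 1-based rightmost base of the right primer site
    tm_left: float
    tm_right: float
    gc_left: float          # percent
    gc_right: float
    product_size: int


@dataclass
class RegionCluster:
    contig_id: str
    members: list = field(default_factory=list)   # (marker_id, start, end)
    span_start: int = 0
    span_end: int = 0

    @property
    def clustered(self) -> bool:
        return len(self.members) >= 2

    @property
    def member_ids(self) -> list:
        return [m[0] for m in self.members]


def primer_tm(seq: str) -> float:
    gc = sum(1 for b in seq if b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def _make_cluster(contig_id, members) -> RegionCluster:
    return RegionCluster(
        contig_id=contig_id,
        members=list(members),
        span_start=min(m[1] for m in members),
        span_end=max(m[2] for m in members),
    )


def _split_infeasible(members, max_product, min_primer_len):
    """Split a chain at its largest internal gaps until a < max_product
    amplicon (span + two minimal primers) can cover each part."""
    span = members[-1][2] - members[0][1] + 1
    if len(members) == 1 or span + 2 * min_primer_len < max_product:
        return [members]
    gaps = [(members[i + 1][1] - members[i][2], i) for i in range(len(members) - 1)]
    _, cut = max(gaps, key=lambda g: (g[0], -g[1]))   # largest gap, leftmost
    left, right = members[:cut + 1], members[cut + 1:]
    return (_split_infeasible(left, max_product, min_primer_len)
            + _split_infeasible(right, max_product, min_primer_len))


def cluster_markers(markers_on_contig, dist_thr: int = 500,
                    max_product: int = 800, min_primer_len: int = 18,
                    contig_id: str = "") -> list[RegionCluster]:
    """Single-linkage chaining of markers into primer regions.

    ``markers_on_contig``: iterable of (marker_id, start, end), any order.
    Adjacent markers with an inter-span distance strictly below ``dist_thr``
    join one chain; chains that no < ``max_product`` bp amplicon can span are
    split greedily at their largest gaps.
    """
    members = sorted(markers_on_contig, key=lambda m: (m[1], m[2], m[0]))
    if not members:
        return []
    chains, chain = [], [members[0]]
    for m in members[1:]:
        if m[1] - chain[-1][2] < dist_thr:
            chain.append(m)
        else:
            chains.append(chain)
            chain = [m]
    chains.append(chain)
    clusters = []
    for chain in chains:
        for part in _split_infeasible(chain, max_product, min_primer_len):
            clusters.append(_make_cluster(contig_id, part))
    return clusters


def _candidate_primers(seq, lo, hi, constraints, is_left):
    """Constraint-satisfying primer windows whose span lies within [lo, hi]
    (0-based half-open on the contig).  Returns (starts, ends, scores) arrays
    of 0-based half-open windows, already filtered on the hard constraints."""
    n = len(seq)
    lo, hi = max(0, lo), min(n, hi)
    if hi - lo < constraints.len_min:
        return np.empty(0, int), np.empty(0, int), np.empty(0, float)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
    is_n = (arr == ord("N")).astype(np.int32)
    cg = np.concatenate(([0], np.cumsum(is_gc)))
    cn = np.concatenate(([0], np.cumsum(is_n)))
    starts_all, ends_all, scores_all = [], [], []
    for L in range(constraints.len_min, constraints.len_max + 1):
        starts = np.arange(lo, hi - L + 1)
        if starts.size == 0:
            continue
        ends = starts + L
        gc = cg[ends] - cg[starts]
        nn = cn[ends] - cn[starts]
        gc_pct = 100.0 * gc / L
        tm = 64.9 + 41.0 * (gc - 16.4) / L
        ok = (nn == 0) & (gc_pct >= constraints.gc_min) & (gc_pct <= constraints.gc_max)
        if not ok.any():
            continue
        starts, ends = starts[ok], ends[ok]
        score = (abs(L - constraints.len_opt)
                 + np.abs(tm[ok] - constraints.tm_opt)
                 + 0.2 * np.abs(gc_pct[ok] - constraints.gc_opt))
        # 3' self-complementarity >= 4 -> primer-dimer prone, reject
        keep = []
        for idx in range(starts.size):
            w = seq[starts[idx]:ends[idx]]
            tail = (w if is_left else revcomp(w))[-4:]
            keep.append(revcomp(tail) != tail)
        keep = np.asarray(keep, bool)
        starts_all.append(starts[keep])
        ends_all.append(ends[keep])
        scores_all.append(score[keep])
    if not starts_all:
        return np.empty(0, int), np.empty(0, int), np.empty(0, float)
    return (np.concatenate(starts_all), np.concatenate(ends_all),
            np.concatenate(scores_all))


def design_primers(region: RegionCluster, contig_seq: str,
                   constraints: PrimerConstraints | None = None) -> PrimerPair | None:
    """Pick the best constraint-satisfying primer pair around a region.

    Singleton regions additionally prefer products near ``product_opt``
    (weight 0.01 per bp); clustered regions only require the product to stay
    strictly below ``clustered_product_max``.  Deterministic: ties break on
    smaller left position, then smaller product.  Returns None when no pair
    satisfies the hard constraints.
    """
    constraints = constraints or PrimerConstraints()
    seq = contig_seq.sequence if hasattr(contig_seq, "sequence") else str(contig_seq)
    n = len(seq)
    rs0, re0 = region.span_start - 1, region.span_end   # 0-based half-open
    if region.clustered:
        pmin, pmax = constraints.product_min, constraints.clustered_product_max - 1
    else:
        pmin, pmax = constraints.product_min, constraints.product_max
    # left primers must end at/before the region start, right ones begin after it
    ls, le, lsc = _candidate_primers(seq, re0 - pmax, rs0, constraints, True)
    rs_, re_, rsc = _candidate_primers(seq, re0, rs0 + pmax, constraints, False)
    if ls.size == 0 or rs_.size == 0:
        return None
    product = re_[None, :] - ls[:, None]          # right_end0 - left_start0
    total = lsc[:, None] + rsc[None, :]
    if not region.clustered:
        total = total + 0.01 * np.abs(product - constraints.product_opt)
    bad = (product < pmin) | (product > pmax) \
        | (rs_[None, :] < le[:, None]) | (re_[None, :] > n)
    total = np.where(bad, np.inf, total)
    best = total.min()
    if not np.isfinite(best):
        return None
    ii, jj = np.where(total <= best + 1e-9)
    order = np.lexsort((product[ii, jj], ls[ii]))
    i, j = ii[order[0]], jj[order[0]]
    lseq = seq[ls[i]:le[i]]
    rseq_site = seq[rs_[j]:re_[j]]
    rseq = revcomp(rseq_site)
    return PrimerPair(
        left_seq=lseq,
        right_seq=rseq,
        left_pos=int(ls[i]) + 1,
        right_pos=int(re_[j]),
        tm_left=primer_tm(lseq),
        tm_right=primer_tm(rseq),
        gc_left=100.0 * sum(1 for b in lseq if b in "GC") / len(lseq),
        gc_right=100.0 * sum(1 for b in rseq if b in "GC") / len(rseq),
        product_size=int(product[i, j]),
    )
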