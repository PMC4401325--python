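"""Microsatellite (SSR) mining.

Detects perfect tandem repeats of 2-8 bp motifs in contigs using the classic
MISA parameterisation: a run qualifies when it reaches a per-motif-length
minimum repeat count (7 for dinucleotides, 5 for tri-, 4 for tetra-, 3 for
penta- through octanucleotides by default).  Runs separated by at most
``compound_gap`` interrupting bases are grouped into compound SSRs.  Motifs
are reported both as observed and as their canonical class — the
lexicographically smallest string over all cyclic rotations of the motif and
of its reverse complement, rendered "canonical/revcomp(canonical)" (so TA, AT
and their complements all report as AT/AT).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP

from .io import Contig

_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MINIMA = {2: 7, 3: 5, 4: 4, 5: 3, 6: 3, 7: 3, 8: 3}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SSRLocus:
    """A detected microsatellite: ``end - start + 1 == unit_len * repeats``."""

    contig_id: str
    start: int             # 1-based inclusive
    end: int               # 1-based inclusive
    motif: str             # repeat unit as observed on the forward strand
    unit_len: int
    repeats: int
    canonical_class: str
    compound_id: str | None = None

    @property
    def span_len(self) -> int:
        return self.end - self.start + 1


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a tandem power of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical class of a repeat motif under rotation and reverse complement."""
    motif = motif.upper()
    if not (2 <= len(motif) <= 8):
        raise ValueError(f"motif length must be 2-8, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not _is_primitive(motif):
        raise ValueError(f"motif {motif!r} is a power of a shorter unit")
    rc = revcomp(motif)
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rc_rotations = [rc[i:] + rc[:i] for i in range(len(rc))]
    canon = min(rotations + rc_rotations)
    # label pairs the canonical motif with the minimal rotation of its
    # reverse complement (AT/AT, AAG/CTT, ATC/ATG ...)
    canon_rc = revcomp(canon)
    partner = min(canon_rc[i:] + canon_rc[:i] for i in range(len(canon_rc)))
    return f"{canon}/{partner}"


def find_ssrs(contig, minima=None, compound_gap: int = 500) -> list[SSRLocus]:
    """Find maximal perfect SSR runs in a contig.

    Overlapping candidate runs of different periods are resolved by keeping
    the longer run, ties broken by smaller start then shorter unit length.
    Runs containing N are discarded.  Consecutive kept loci separated by at
    most ``compound_gap`` bases share a compound id.
    """
    if isinstance(contig, Contig):
        seq, contig_id = contig.sequence, contig.id
    else:
        seq, contig_id = str(contig).upper(), ""
    minima = dict(DEFAULT_MINIMA if minima is None else minima)
    n = len(seq)

    candidates = []  # (start0, end0_exclusive, unit_len, repeats, motif)
    for k in sorted(minima):
        min_reps = minima[k]
        limit = n - k
        j = 0
        while j < limit:
            c = seq[j]
            if c == seq[j + k] and c != "N":
                a = j
                while j < limit and seq[j] == seq[j + k] and seq[j] != "N":
                    j += 1
                reps = (j - a + k) // k
                if reps >= min_reps:
                    motif = seq[a:a + k]
                    if "N" not in motif and _is_primitive(motif):
                        candidates.append((a, a + reps * k, k, reps, motif))
            else:
                j += 1

    # overlap resolution: longer run wins; ties -> smaller start, shorter unit
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    kept: list[tuple] = []
    for cand in candidates:
        a, b = cand[0], cand[1]
        if all(b <= o[0] or a >= o[1] for o in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c[0])

    loci = [
        SSRLocus(
            contig_id=contig_id,
            start=a + 1,
            end=b,
            motif=motif,
            unit_len=k,
            repeats=reps,
            canonical_class=canonical_motif(motif),
        )
        for a, b, k, reps, motif in kept
    ]

    # compound grouping: gap between consecutive loci <= compound_gap
    group: list[int] = []
    groups: list[list[int]] = []
    for i, locus in enumerate(loci):
        if group and locus.start - loci[group[-1]].end - 1 <= compound_gap:
            group.append(i)
        else:
            if len(group) > 1:
                groups.append(group)
            group = [i]
    if len(group) > 1:
        groups.append(group)
    for gnum, members in enumerate(groups, start=1):
        cid = f"{contig_id}.c{gnum}" if contig_id else f"c{gnum}"
        for i in members:
            loci[i] = replace(loci[i], compound_id=cid)
    return loci


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SSRSummary:
    n_total: int
    n_compound: int
    unit_len_pct: dict
    class_pct: dict
    frequency_kb: float | None     # kb of sequence per SSR
    frequency_label: str           # "1/X kb" or "NA"


def ssr_summary(loci, total_len_kb: float) -> SSRSummary:
    """Per-library SSR bookkeeping: counts, motif spectra and density."""
    if total_len_kb <= 0:
        raise ValueError("total_len_kb must be positive")
    n = len(loci)
    if n == 0:
        return SSRSummary(0, 0, {}, {}, None, "NA")
    n_compound = sum(1 for l in loci if l.compound_id is not None)
    unit_counts: dict[int, int] = {}
    class_counts: dict[str, int] = {}
    for l in loci:
        unit_counts[l.unit_len] = unit_counts.get(l.unit_len, 0) + 1
        class_counts[l.canonical_class] = class_counts.get(l.canonical_class, 0) + 1
    unit_pct = {k: _round2(100.0 * v / n) for k, v in sorted(unit_counts.items())}
    class_pct = {k: _round2(100.0 * v / n) for k, v in sorted(class_counts.items())}
    freq = _round2(total_len_kb / n)
    return SSRSummary(n, n_compound, unit_pct, class_pct, freq, f"1/{freq:.2f} kb")
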