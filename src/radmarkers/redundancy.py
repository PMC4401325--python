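"""Novelty screening of candidate SSR markers against a known-marker database.

A candidate is redundant with the published marker collection when, after the
SSR itself is masked out of its marker region, the remaining (unique) sequence
still shares >= 50 matched bases with some database record.  "Matched bases"
is read as the identity count of the single best local alignment against a
record; masked N positions never count as matches.  The redundancy decision
is monotone in database content: it is true as soon as ANY record reaches the
matched-base threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AnchorMatch, SeqCollection, match_sort_key
from .io import read_fasta


@dataclass
class KnownMarkerDB:
    """Published marker sequences (id -> sequence)."""

    records: dict

    def __post_init__(self):
        if len(set(self.records)) != len(self.records):
            raise ValueError("duplicate record ids")
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
        self._collection = SeqCollection(self.records)

    @property
    def total_len(self) -> int:
        return self._collection.total_len

    @classmethod
    def from_fasta(cls, path) -> "KnownMarkerDB":
        return cls({c.id: c.sequence for c in read_fasta(path)})


def interprimer_sequence(primer_pair, contig) -> str:
    """The contig sub-sequence spanned by a primer pair, primer sites included."""
    seq = contig.sequence if hasattr(contig, "sequence") else str(contig)
    left_start = primer_pair.left_pos
    right_end = primer_pair.right_pos
    left_end = left_start + len(primer_pair.left_seq) - 1
    right_start = right_end - len(primer_pair.right_seq) + 1
    if left_start < 1 or right_end > len(seq):
        raise ValueError("primer pair extends beyond the contig")
    if right_start <= left_end:
        raise ValueError("right primer does not lie after the left primer")
    return seq[left_start - 1:right_end]


def mask_ssr(sequence: str, ssr_spans) -> str:
    """Replace every 1-based-inclusive SSR span with N; length preserved."""
    masked = list(sequence)
    for start, end in ssr_spans:
        if start < 1 or end > len(sequence) or end < start:
            raise ValueError(f"SSR span ({start}, {end}) outside sequence")
        for i in range(start - 1, end):
            masked[i] = "N"
    return "".join(masked)


def is_redundant(masked_seq: str, db: KnownMarkerDB, matched_min: int = 50,
                 evalue_max: float = 10.0) -> tuple[bool, AnchorMatch | None]:
    """Redundancy decision plus the best supporting hit.

    Redundant iff some database record reaches ``matched_min`` identities in
    its best local alignment with the masked sequence.  The returned hit is
    the tie-break-best among threshold-meeting hits when redundant, else the
    overall best (or None when nothing seeds).
    """
    if set(masked_seq) <= {"N"} or not masked_seq:
        return False, None   # nothing alignable: automatically novel
    hits = db._collection.search(masked_seq, evalue_max=evalue_max)
    if not hits:
        return False, None
    meeting = [h for h in hits if h.identities >= matched_min]
    if meeting:
        meeting.sort(key=match_sort_key)
        return True, meeting[0]
    return False, hits[0]
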