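"""Seeded local alignment of short flanking sequences, with E-values.

A BLAST-like search tuned for short, high-identity nucleotide flanks: a pair
is considered only if query and subject share an exact 11-mer word (on either
strand); seeded pairs are then scored with a full affine-gap Smith-Waterman
(match +1, mismatch -2, gap of length L costs 5 + 2L), so the returned score
is the exact local optimum whenever any seed exists, and no hit is reported
otherwise.  Expectation values use the standard extreme-value form
E = K * m * n * exp(-lambda * S) with the ungapped nucleotide constants
K = 0.711, lambda = 1.37, applied to gapped scores as an approximation.

N bases never match anything (they score as mismatches and are excluded from
seed words), so masked positions cannot contribute matched bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .ssr import revcomp

WORD_SIZE = 11
K_DEFAULT = 0.711
LAMBDA_DEFAULT = 1.37

DEFAULT_SCORING = {"match": 1, "mismatch": -2, "gap_open": -5, "gap_extend": -2}

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AnchorMatch:
    """A local alignment linking a query to a subject sequence."""

    query_id: str
    subject_id: str
    q_start: int     # 1-based inclusive, always on the forward query
    q_end: int
    s_start: int
    s_end: int
    strand: str      # '+' or '-'
    score: int
    identities: int
    evalue: float

    @property
    def matched_bases(self) -> int:
        """Identities: the quantity of the >=50-matched-bases redundancy rule."""
        return self.identities


def evalue(score: float, q_len: int, db_len: int,
           K: float = K_DEFAULT, lam: float = LAMBDA_DEFAULT) -> float:
    """Karlin-Altschul expectation: E = K * m * n * exp(-lambda * S)."""
    if q_len < 1 or db_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    return K * q_len * db_len * math.exp(-lam * score)


@njit(cache=False)
def _sw_fill(q, s, match, mismatch, gopen1, gext):  # pragma: no cover - jitted
    n = q.size
    m = s.size
    NEG = -1_000_000
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - gopen1
            t = E[i, j - 1] - gext
            if t > e:
                e = t
            E[i, j] = e
            f = H[i - 1, j] - gopen1
            t = F[i - 1, j] - gext
            if t > f:
                f = t
            F[i, j] = f
            if qi == s[j - 1] and qi < 4:
                sc = match
            else:
                sc = mismatch
            v = H[i - 1, j - 1] + sc
            if v < 0:
                v = 0
            if e > v:
                v = e
            if f > v:
                v = f
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(q, s, H, E, F, bi, bj, match, mismatch, gopen1, gext):
    """Walk back from the best cell; returns (q_start0, s_start0, identities)."""
    i, j = bi, bj
    state = 0  # 0=H, 1=E (gap in query / move left), 2=F (gap in subject / up)
    ident = 0
    while True:
        if state == 0:
            v = H[i, j]
            if v == 0:
                break
            eq = q[i - 1] == s[j - 1] and q[i - 1] < 4
            sc = match if eq else mismatch
            if v == H[i - 1, j - 1] + sc:
                if eq:
                    ident += 1
                i -= 1
                j -= 1
            elif v == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i, j - 1] - gopen1:
                state = 0
            j -= 1
        else:
            if F[i, j] == H[i - 1, j] - gopen1:
                state = 0
            i -= 1
    return i, j, ident


def _words(seq: str, word_size: int) -> set[str]:
    return {
        seq[i:i + word_size]
        for i in range(len(seq) - word_size + 1)
        if "N" not in seq[i:i + word_size]
    }


def _align_one_strand(qseq: str, sseq: str, scoring):
    match, mismatch = scoring["match"], scoring["mismatch"]
    gopen1 = -(scoring["gap_open"] + scoring["gap_extend"])
    gext = -scoring["gap_extend"]
    q = _encode(qseq)
    s = _encode(sseq)
    H, E, F, best, bi, bj = _sw_fill(q, s, match, mismatch, gopen1, gext)
    if best <= 0:
        return None
    qi0, sj0, ident = _traceback(q, s, H, E, F, bi, bj, match, mismatch, gopen1, gext)
    return best, qi0 + 1, bi, sj0 + 1, bj, ident  # 1-based inclusive spans


def local_align(query: str, subject: str, scoring=None, *,
                word_size: int = WORD_SIZE, db_len: int | None = None,
                query_id: str = "query", subject_id: str = "subject",
                K: float = K_DEFAULT, lam: float = LAMBDA_DEFAULT):
    """Best seeded local alignment of query vs subject, or None without a seed.

    Both strands of the query are searched; the higher-scoring strand wins
    (ties go to '+').  ``db_len`` sets the search-space size used for the
    E-value (defaults to the subject length).
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    scoring = dict(DEFAULT_SCORING if scoring is None else scoring)
    sub_words = _words(subject, word_size)
    qlen = len(query)
    best = None
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        if not (_words(qseq, word_size) & sub_words):
            continue
        res = _align_one_strand(qseq, subject, scoring)
        if res is None:
            continue
        score, qs, qe, ss, se, ident = res
        if strand == "-":
            qs, qe = qlen - qe + 1, qlen - qs + 1
        if best is None or score > best[0]:
            best = (score, qs, qe, ss, se, ident, strand)
    if best is None:
        return None
    score, qs, qe, ss, se, ident, strand = best
    ev = evalue(score, qlen, db_len if db_len is not None else len(subject), K, lam)
    return AnchorMatch(
        query_id=query_id, subject_id=subject_id,
        q_start=qs, q_end=qe, s_start=ss, s_end=se,
        strand=strand, score=score, identities=ident, evalue=ev,
    )


def match_sort_key(m: AnchorMatch):
    """Tie-break among hits: smallest E-value, longest identities, subject id."""
    return (m.evalue, -m.identities, m.subject_id)


class SeqCollection:
    """A word-indexed set of subject sequences for seeded many-vs-one search."""

    def __init__(self, seqs: dict[str, str], word_size: int = WORD_SIZE):
        self.seqs = dict(seqs)
        self.word_size = word_size
        self.total_len = sum(len(s) for s in self.seqs.values())
        self._index: dict[str, set[str]] = {}
        for sid, s in self.seqs.items():
            for w in _words(s, word_size):
                self._index.setdefault(w, set()).add(sid)

    def candidate_ids(self, query: str) -> set[str]:
        hits: set[str] = set()
        for qseq in (query, revcomp(query)):
            for w in _words(qseq, self.word_size):
                if w in self._index:
                    hits |= self._index[w]
        return hits

    def search(self, query: str, scoring=None, *, query_id: str = "query",
               evalue_max: float | None = None) -> list[AnchorMatch]:
        """All seeded hits of the query against the collection, best first."""
        matches = []
        for sid in sorted(self.candidate_ids(query)):
            m = local_align(
                query, self.seqs[sid], scoring,
                word_size=self.word_size, db_len=max(self.total_len, 1),
                query_id=query_id, subject_id=sid,
            )
            if m is None:
                continue
            if evalue_max is not None and m.evalue > evalue_max:
                continue
            matches.append(m)
        matches.sort(key=match_sort_key)
        return matches
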