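"""Independent oracles used only by the test suite.

The SSR oracle enumerates every (start, unit-length) pair directly; the
alignment oracle is Biopython's PairwiseAligner configured to the same
scoring scheme.  Neither shares code with the implementation under test.
"""

from Bio import Align

DEFAULT_MINIMA = {2: 7, 3: 5, 4: 4, 5: 3, 6: 3, 7: 3, 8: 3}

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq):
    return seq.translate(_COMP)[::-1]


def _primitive(motif):
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d)
                   for d in range(1, n))


def brute_find_ssrs(seq, minima=None):
    """Exhaustive SSR scan: returns [(start1, end1, motif, repeats)] after the
    same longest-run overlap resolution and compound grouping policy."""
    minima = minima or DEFAULT_MINIMA
    n = len(seq)
    cands = []
    for k, min_reps in minima.items():
        for i in range(n - k + 1):
            motif = seq[i:i + k]
            if "N" in motif or not _primitive(motif):
                continue
            # maximal start: the period-k match region must not extend left
            if i > 0 and i - 1 + k < n and seq[i - 1] == seq[i - 1 + k] \
                    and seq[i - 1] != "N":
                continue
            r = 1
            while seq[i + r * k:i + (r + 1) * k] == motif:
                r += 1
            if r >= min_reps:
                cands.append((i, i + r * k, k, r, motif))
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    kept = []
    for c in cands:
        if all(c[1] <= o[0] or c[0] >= o[1] for o in kept):
            kept.append(c)
    kept.sort(key=lambda c: c[0])
    return [(a + 1, b, motif, r) for a, b, k, r, motif in kept]


def make_aligner():
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -7     # first gapped base: open (5) + extend (2)
    al.extend_gap_score = -2
    return al


def oracle_best_local_score(a, b):
    """Exact local-alignment optimum over both strands."""
    al = make_aligner()
    return max(al.score(a, b), al.score(rc(a), b))


def shares_word(a, b, w=11):
    words_b = {b[i:i + w] for i in range(len(b) - w + 1) if "N" not in b[i:i + w]}
    for q in (a, rc(a)):
        for i in range(len(q) - w + 1):
            word = q[i:i + w]
            if "N" not in word and word in words_b:
                return True
    return False
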