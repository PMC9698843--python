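"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: alignment scores come
from exhaustive enumeration of alignment paths, motif hits from per-window
checks, and translation from a literal codon dictionary.
"""

from functools import lru_cache

# literal standard codon table (independent of any library)
CODON = {}
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG")
_i = 0
for _a in _BASES:
    for _b in _BASES:
        for _c in _BASES:
            CODON[_a + _b + _c] = _AAS[_i]
            _i += 1

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_oracle(seq, frame):
    s = seq.upper()
    if frame < 0:
        s = "".join(COMPLEMENT[c] for c in reversed(s))
    s = s[abs(frame) - 1:]
    out = []
    for k in range(0, len(s) - len(s) % 3, 3):
        out.append(CODON.get(s[k:k + 3], "X"))
    return "".join(out)


def gap_cost(length, gap_open, gap_extend):
    return gap_open + gap_extend * length if length else 0.0


def global_score_oracle(q, s, score_fn, gap_open, gap_extend):
    """Exhaustive recursion over all global alignments with affine gaps."""

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        # state: 0 = free/diagonal, 1 = in query gap (consuming s),
        #        2 = in subject gap (consuming q)
        if i == len(q) and j == len(s):
            return 0.0
        best = -1e30
        if i < len(q) and j < len(s):
            best = max(best, score_fn(q[i], s[j]) + rec(i + 1, j + 1, 0))
        if j < len(s):
            open_cost = gap_extend + (gap_open if state != 1 else 0.0)
            best = max(best, -open_cost + rec(i, j + 1, 1))
        if i < len(q):
            open_cost = gap_extend + (gap_open if state != 2 else 0.0)
            best = max(best, -open_cost + rec(i + 1, j, 2))
        return best

    return rec(0, 0, 0)


def local_score_oracle(q, s, score_fn, gap_open, gap_extend):
    """Best score over all local alignments: enumerate all substring pairs
    and take the best global alignment score of each pair (empty = 0)."""
    best = 0.0
    for i0 in range(len(q) + 1):
        for i1 in range(i0 + 1, len(q) + 1):
            for j0 in range(len(s) + 1):
                for j1 in range(j0 + 1, len(s) + 1):
                    sc = global_score_oracle(
                        q[i0:i1], s[j0:j1], score_fn, gap_open, gap_extend
                    )
                    best = max(best, sc)
    return best


def scan_oracle(protein, elements):
    """Position-by-position window check; elements as in MotifPattern."""
    hits = []
    m = len(elements)
    for start in range(len(protein) - m + 1):
        window = protein[start:start + m]
        if all(e is None or c in e for c, e in zip(window, elements)):
            hits.append((start + 1, start + m, window))
    return hits
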