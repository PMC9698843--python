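"""Exact pairwise protein alignment and homology anchoring onto genomic frames.

Local (Smith-Waterman) and global (Needleman-Wunsch) alignment under an
affine gap model: a gap of length k costs ``gap_open + k * gap_extend``
(BLAST convention, defaults 11/1 with BLOSUM62). The dynamic programs are
exact, with a deterministic traceback that prefers diagonal, then up
(gap in the subject row), then left. Identity and coverage statistics follow
BLAST tabular conventions: percent identity is identities over all alignment
columns including gaps, rounded half-up to 2 decimals; query cover is the
aligned query span over the query length, rounded half-up to a whole percent.

``anchor_protein_to_genome`` is the entry point for homology-anchored gene
reconstruction: it translates a contig in all six frames, finds every local
alignment of a reference protein above a score threshold, and splits
alignments at long gap runs (the footprint of an intervening intron in a
genomic frame) into coding segments with back-mapped nucleotide coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import GenomicContig, ProteinSeq, translate

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_MIN_SEGMENT_SCORE = 50.0
DEFAULT_MAX_GAP_COLS = 10
STOP_ALIGN_SCORE = -100.0

_NEG = -1e30


class SubstitutionMatrix:
    """A residue substitution matrix with an index for fast lookup."""

    def __init__(self, alphabet: str, scores: np.ndarray, name: str = "custom"):
        self.alphabet = alphabet
        self.index = {c: i for i, c in enumerate(alphabet)}
        self.scores = np.asarray(scores, dtype=np.float64)
        self.name = name

    @classmethod
    def load(cls, name: str = DEFAULT_MATRIX) -> "SubstitutionMatrix":
        m = substitution_matrices.load(name)
        return cls("".join(m.alphabet), np.array(m, dtype=np.float64), name)

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([self.index[c] for c in seq], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} not in matrix {self.name!r} alphabet"
            ) from None

    def pair_score(self, a: str, b: str) -> float:
        return float(self.scores[self.index[a], self.index[b]])


_MATRIX_CACHE: dict[str, SubstitutionMatrix] = {}


def get_matrix(matrix) -> SubstitutionMatrix:
    if isinstance(matrix, SubstitutionMatrix):
        return matrix
    if matrix not in _MATRIX_CACHE:
        _MATRIX_CACHE[matrix] = SubstitutionMatrix.load(matrix)
    return _MATRIX_CACHE[matrix]


@dataclass
class AlignmentResult:
    """One pairwise alignment with BLAST-style summary statistics.

    Intervals are 1-based inclusive residue positions; an empty alignment
    (possible for local alignment of unrelated sequences) has zero-length
    intervals encoded as (0, -1) and score 0.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    score: float
    n_identical: int
    n_columns: int
    percent_identity: float
    query_cover: int
    query_aln: str
    subject_aln: str

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@njit(cache=False)
def _affine_dp(q, s, sub, gap_open, gap_ext, is_local):  # pragma: no cover
    n = q.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)  # ends with gap in query row (left move)
    F = np.full((n + 1, m + 1), _NEG)  # ends with gap in subject row (up move)
    if not is_local:
        for j in range(1, m + 1):
            H[0, j] = -(gap_open + gap_ext * j)
            E[0, j] = H[0, j]
        for i in range(1, n + 1):
            H[i, 0] = -(gap_open + gap_ext * i)
            F[i, 0] = H[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open - gap_ext
            e2 = E[i, j - 1] - gap_ext
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_ext
            f2 = F[i - 1, j] - gap_ext
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if is_local and h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


def _traceback(q_enc, s_enc, q_str, s_str, H, E, F, sub, go, ge, local,
               start_i, start_j):
    """Deterministic traceback: prefer diagonal, then up, then left."""
    i, j = start_i, start_j
    qa: list[str] = []
    sa: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if local and H[i, j] == 0.0:
                break
            if i == 0 and j == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[
                q_enc[i - 1], s_enc[j - 1]
            ]:
                qa.append(q_str[i - 1])
                sa.append(s_str[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:
                raise AssertionError("traceback lost: inconsistent DP matrices")
        elif state == "F":  # consume query residue, gap in subject row
            qa.append(q_str[i - 1])
            sa.append("-")
            if F[i, j] == H[i - 1, j] - go - ge:
                state = "H"  # gap opens here; prefer closing on ties
            i -= 1
        else:  # "E": consume subject residue, gap in query row
            qa.append("-")
            sa.append(s_str[j - 1])
            if E[i, j] == H[i, j - 1] - go - ge:
                state = "H"
            j -= 1
    qa.reverse()
    sa.reverse()
    return "".join(qa), "".join(sa), i, j


def _make_result(query, subject, q_aln, s_aln, q_from, s_from, score) -> AlignmentResult:
    n_cols = len(q_aln)
    n_id = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-")
    q_span = sum(1 for c in q_aln if c != "-")
    s_span = sum(1 for c in s_aln if c != "-")
    if n_cols == 0:
        qs = ss = 0
        qe = se = -1
        pid = 0.0
        cover = 0
    else:
        qs = q_from + 1 if q_span else 0
        qe = q_from + q_span if q_span else -1
        ss = s_from + 1 if s_span else 0
        se = s_from + s_span if s_span else -1
        pid = _round_half_up(100.0 * n_id / n_cols, 2)
        cover = int(_round_half_up(100.0 * q_span / len(query.seq), 0)) if query.seq else 0
    return AlignmentResult(
        query_id=query.id,
        subject_id=subject.id,
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
        score=float(score),
        n_identical=n_id,
        n_columns=n_cols,
        percent_identity=pid,
        query_cover=cover,
        query_aln=q_aln,
        subject_aln=s_aln,
    )


def align_local(
    q: ProteinSeq,
    s: ProteinSeq,
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with affine gaps.

    The traceback starts at the highest-scoring cell (ties: smallest query
    position, then smallest subject position) and prefers diagonal over up
    over left moves, so results are fully deterministic.
    """
    if not q.seq or not s.seq:
        raise ValueError("align_local requires non-empty sequences")
    mat = get_matrix(matrix)
    qe, se = mat.encode(q.seq), mat.encode(s.seq)
    H, E, F = _affine_dp(qe, se, mat.scores, float(gap_open), float(gap_extend), True)
    best = H.max()
    if best <= 0.0:
        return _make_result(q, s, "", "", 0, 0, 0.0)
    # ties: smallest i then j
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    q_aln, s_aln, i0, j0 = _traceback(
        qe, se, q.seq, s.seq, H, E, F, mat.scores,
        float(gap_open), float(gap_extend), True, int(i), int(j)
    )
    return _make_result(q, s, q_aln, s_aln, i0, j0, best)


def align_global(
    q: ProteinSeq,
    s: ProteinSeq,
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment (end-to-end) with affine gaps."""
    mat = get_matrix(matrix)
    if not q.seq and not s.seq:
        raise ValueError("align_global requires at least one non-empty sequence")
    qe, se = mat.encode(q.seq), mat.encode(s.seq)
    H, E, F = _affine_dp(qe, se, mat.scores, float(gap_open), float(gap_extend), False)
    n, m = len(q.seq), len(s.seq)
    q_aln, s_aln, i0, j0 = _traceback(
        qe, se, q.seq, s.seq, H, E, F, mat.scores,
        float(gap_open), float(gap_extend), False, n, m
    )
    return _make_result(q, s, q_aln, s_aln, i0, j0, H[n, m])


# ---------------------------------------------------------------------------
# Homology anchoring
# ---------------------------------------------------------------------------

def _iter_local_hits(ref, frame_prot, mat, gap_open, gap_extend, min_score):
    """All disjoint local alignments of ref vs frame_prot scoring >= min_score.

    Finds the best hit, then recurses on the subject regions to its left and
    right (the query may be reused by several exon blocks in one frame).
    Subject coordinates in the returned results are 1-based in frame_prot.
    """
    hits = []
    stack = [(0, len(frame_prot.seq))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        window = ProteinSeq(frame_prot.id, frame_prot.seq[lo:hi], is_raw_frame=True)
        if not window.seq:
            continue
        res = align_local(ref, window, mat, gap_open, gap_extend)
        if res.is_empty or res.score < min_score:
            continue
        res.subject_start += lo
        res.subject_end += lo
        res.subject_id = frame_prot.id
        hits.append(res)
        stack.append((lo, res.subject_start - 1 + 0))  # left of hit (0-based hi)
        stack.append((res.subject_end, hi))
    hits.sort(key=lambda r: r.subject_start)
    return hits


def _split_alignment(res: AlignmentResult, max_gap_cols: int):
    """Split an alignment at runs of >= max_gap_cols gap columns.

    Yields (q_aln, s_aln, q_offset, s_offset) blocks with boundary gap
    columns trimmed; offsets count residues consumed before the block.
    """
    cols = list(zip(res.query_aln, res.subject_aln))
    gap = [a == "-" or b == "-" for a, b in cols]
    # mark separator columns: maximal gap runs of length >= max_gap_cols
    sep = [False] * len(cols)
    i = 0
    while i < len(cols):
        if gap[i]:
            j = i
            while j < len(cols) and gap[j]:
                j += 1
            if j - i >= max_gap_cols:
                for k in range(i, j):
                    sep[k] = True
            i = j
        else:
            i += 1
    q_consumed = res.query_start - 1
    s_consumed = res.subject_start - 1
    block: list[tuple[str, str]] = []
    block_q0 = q_consumed
    block_s0 = s_consumed
    for idx, (a, b) in enumerate(cols):
        if sep[idx]:
            if block:
                yield _trim_block(block, block_q0, block_s0)
                block = []
        else:
            if not block:
                block_q0, block_s0 = q_consumed, s_consumed
            block.append((a, b))
        if a != "-":
            q_consumed += 1
        if b != "-":
            s_consumed += 1
    if block:
        yield _trim_block(block, block_q0, block_s0)


def _trim_block(block, q0, s0):
    lead = 0
    while lead < len(block) and ("-" in block[lead]):
        a, b = block[lead]
        if a != "-":
            q0 += 1
        if b != "-":
            s0 += 1
        lead += 1
    tail = len(block)
    while tail > lead and ("-" in block[tail - 1]):
        tail -= 1
    trimmed = block[lead:tail]
    qa = "".join(a for a, _ in trimmed)
    sa = "".join(b for _, b in trimmed)
    return qa, sa, q0, s0


def _column_scores(qa, sa, mat, gap_open, gap_extend):
    """Per-column scores; a gap run's opening cost falls on its first column."""
    w = []
    in_gap = False
    for a, b in zip(qa, sa):
        if a == "-" or b == "-":
            w.append(-(gap_extend + (gap_open if not in_gap else 0.0)))
            in_gap = True
        else:
            w.append(mat.pair_score(a, b))
            in_gap = False
    return w


def _max_subarray_trim(qa, sa, q0, s0, mat, gap_open, gap_extend, baseline):
    """Trim block ends to the maximum-scoring column run.

    A Smith-Waterman optimum never ends on a net-negative run, so raw blocks
    can retain sparsely matching junk at their ends (translated intron or
    off-frame sequence). Subtracting a per-column ``baseline`` before taking
    the best-scoring contiguous run removes runs whose match density is far
    below a genuine homologous block's.
    """
    w = [x - baseline for x in
         _column_scores(qa, sa, mat, gap_open, gap_extend)]
    best_sum = cur = 0.0
    best = (0, 0)  # [i, j) of best window
    cur_start = 0
    for k, x in enumerate(w):
        if cur <= 0.0:
            cur = x
            cur_start = k
        else:
            cur += x
        if cur > best_sum:
            best_sum = cur
            best = (cur_start, k + 1)
    i, j = best
    if i == 0 and j == len(w):
        return qa, sa, q0, s0
    for a, b in zip(qa[:i], sa[:i]):
        if a != "-":
            q0 += 1
        if b != "-":
            s0 += 1
    return qa[i:j], sa[i:j], q0, s0


def _score_block(qa, sa, mat, gap_open, gap_extend) -> float:
    score = 0.0
    run = 0
    for a, b in zip(qa, sa):
        if a == "-" or b == "-":
            run += 1
        else:
            if run:
                score -= gap_open + gap_extend * run
                run = 0
            score += mat.pair_score(a, b)
    if run:
        score -= gap_open + gap_extend * run
    return score


def anchor_protein_to_genome(
    ref: ProteinSeq,
    contig: GenomicContig,
    min_segment_score: float = DEFAULT_MIN_SEGMENT_SCORE,
    matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    max_gap_cols: int = DEFAULT_MAX_GAP_COLS,
    trim_baseline: float = 1.0,
) -> list:
    """Anchor a reference protein onto a contig's six translation frames.

    Returns CodingSegment objects (sorted by genomic start) whose peptides
    are the homologous blocks of the translated frames; a long gap run inside
    one frame alignment (>= max_gap_cols columns) is taken as the footprint
    of an intervening intron and splits the alignment into separate segments.
    """
    from .genemodel import CodingSegment  # local import: genemodel imports us

    if len(contig.seq) < 3:
        raise ValueError("contig shorter than one codon")
    mat = get_matrix(matrix)
    # a translated stop can never lie inside a real coding exon, so make
    # aligning anything onto '*' prohibitive (junk-translation firewall)
    if "*" in mat.index:
        scores = mat.scores.copy()
        k = mat.index["*"]
        scores[k, :] = scores[:, k] = STOP_ALIGN_SCORE
        mat = SubstitutionMatrix(mat.alphabet, scores, f"{mat.name}|nostop")
    L = len(contig.seq)
    segments = []
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate(contig.seq, frame, record_id=f"{contig.id}|frame{frame}")
        if not prot.seq:
            continue
        for hit in _iter_local_hits(ref, prot, mat, gap_open, gap_extend,
                                    min_segment_score):
            for qa, sa, q0, s0 in _split_alignment(hit, max_gap_cols):
                if not qa:
                    continue
                qa, sa, q0, s0 = _max_subarray_trim(
                    qa, sa, q0, s0, mat, gap_open, gap_extend, trim_baseline
                )
                if not qa:
                    continue
                score = _score_block(qa, sa, mat, gap_open, gap_extend)
                if score < min_segment_score:
                    continue
                s_span = sum(1 for c in sa if c != "-")
                p1 = s0 + 1              # 1-based first peptide pos in frame
                p2 = s0 + s_span
                f = abs(frame)
                if frame > 0:
                    nt_start = f + 3 * (p1 - 1)
                    nt_end = f + 3 * (p2 - 1) + 2
                    strand = "+"
                else:
                    nt_start = L - (f + 3 * (p2 - 1) + 2) + 1
                    nt_end = L - (f + 3 * (p1 - 1)) + 1
                    strand = "-"
                peptide = sa.replace("-", "")
                n_id = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
                anchor = AlignmentResult(
                    query_id=ref.id,
                    subject_id=prot.id,
                    query_start=q0 + 1,
                    query_end=q0 + sum(1 for c in qa if c != "-"),
                    subject_start=p1,
                    subject_end=p2,
                    score=score,
                    n_identical=n_id,
                    n_columns=len(qa),
                    percent_identity=_round_half_up(100.0 * n_id / len(qa), 2),
                    query_cover=int(_round_half_up(
                        100.0 * sum(1 for c in qa if c != "-") / len(ref.seq), 0)),
                    query_aln=qa,
                    subject_aln=sa,
                )
                segments.append(
                    CodingSegment(
                        contig_id=contig.id,
                        strand=strand,
                        frame=frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        peptide=peptide,
                        anchor=anchor,
                    )
                )
    segments.sort(key=lambda s: (s.nt_start, s.nt_end))
    return segments
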