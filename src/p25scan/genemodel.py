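"""Gene-model reconstruction from homology-anchored coding segments.

The reconstruction logic mirrors how a curator assembles a gene model by
hand from TBLASTN-style hits: two homologous coding blocks separated by a
genomic gap whose length is not divisible by three cannot lie in one reading
frame, so the gap is evidence of an intron; the intron's phase follows from
the cumulative coding length upstream of it; start codons are enumerated
upstream and the C-terminus is completed by scanning to the first in-frame
stop codon. All coordinates are 1-based inclusive on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .seqio import GenomicContig, ProteinSeq, reverse_complement, translate
from . import pairwise

DEFAULT_SLIDE_MAX = 6
DEFAULT_STOP_SCAN_LIMIT = 3000
STOP_CODONS = {"TAA", "TAG", "TGA"}


class MergeConflictError(ValueError):
    """Overlapping partial proteins disagree inside the overlap."""


@dataclass
class CodingSegment:
    """A homology-anchored translated block on a contig.

    ``nt_start``/``nt_end`` are forward-strand coordinates even for
    reverse-strand segments (``strand == '-'``); the span is always a whole
    number of codons and translates (on its own strand) to ``peptide``.
    """

    contig_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    peptide: str
    anchor: Optional[pairwise.AlignmentResult] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if (self.nt_end - self.nt_start + 1) % 3 != 0:
            raise ValueError(
                f"segment {self.nt_start}..{self.nt_end} is not a whole "
                "number of codons"
            )

    def __len__(self) -> int:
        return self.nt_end - self.nt_start + 1

    def validate_against(self, contig: GenomicContig) -> None:
        dna = contig.subseq(self.nt_start, self.nt_end)
        if self.strand == "-":
            dna = reverse_complement(dna)
        if translate(dna).seq != self.peptide:
            raise ValueError(
                f"segment {self.nt_start}..{self.nt_end} does not translate "
                "to its peptide"
            )


@dataclass
class IntronCall:
    """An inferred intron with its phase and supporting evidence.

    Phase n means the intron interrupts a codon after n of its bases
    (phase 0 = between codons). ``evidence`` is a subset of
    {"frame_shift", "splice_motif", "homolog_boundary"}.
    """

    nt_start: int
    nt_end: int
    phase: int
    evidence: set = field(default_factory=set)
    donor: str = ""
    acceptor: str = ""

    @property
    def length(self) -> int:
        return self.nt_end - self.nt_start + 1


@dataclass
class StartCodon:
    nt_start: int
    nt_end: int
    in_frame: bool


@dataclass
class GeneModel:
    contig_id: str
    strand: str
    exons: list  # list of (nt_start, nt_end), ascending, non-overlapping
    introns: list  # list of IntronCall
    start_candidates: list  # list of StartCodon
    cds: str
    protein: ProteinSeq
    n_terminus_missing: bool
    c_terminus_missing: bool
    n_terminus_ambiguous: bool = False
    extra_upstream_exon_hypothesized: bool = False
    notes: list = field(default_factory=list)

    @property
    def n_exons_supported(self) -> int:
        return len(self.exons)

    @property
    def n_exons_hypothesized(self) -> int:
        return len(self.exons) + (1 if self.extra_upstream_exon_hypothesized else 0)


@dataclass
class IntronSupport:
    intron_index: int
    supported: bool
    homolog_index: Optional[int] = None
    column_distance: Optional[int] = None
    note: str = ""


def gap_frame_shift(upstream: CodingSegment, downstream: CodingSegment):
    """Length of the genomic gap between two segments and its frame offset.

    A non-zero frame offset (gap length mod 3) means the two blocks cannot
    belong to one uninterrupted reading frame — the frame-shift evidence for
    an intervening intron.
    """
    if upstream.contig_id != downstream.contig_id:
        raise ValueError("segments lie on different contigs")
    if upstream.strand != downstream.strand:
        raise ValueError("segments lie on different strands")
    if upstream.nt_end >= downstream.nt_start:
        raise ValueError(
            f"segments overlap or are out of order "
            f"({upstream.nt_end} >= {downstream.nt_start})"
        )
    gap_length = downstream.nt_start - upstream.nt_end - 1
    return gap_length, gap_length % 3


def _splice_candidates(contig, g_lo, g_hi, slide_max):
    """(s, e) slides of the default intron boundaries hitting GT...AG.

    Positive slides re-assign gap bases to the flanking exons; negative
    slides re-assign anchored exon bases to the intron (repairing anchors
    over-extended by coincidental residue matches). The total slide must be
    a multiple of 3 so the coding length mod 3 is unchanged.
    """
    n = len(contig.seq)
    out = []
    for s in range(-slide_max, slide_max + 1):
        start = g_lo + s
        if start < 1 or start + 1 > n:
            continue
        if contig.subseq(start, start + 1) != "GT":
            continue
        for e in range(-slide_max, slide_max + 1):
            end = g_hi - e
            if end > n or end - 1 < start + 2:
                continue
            if (s + e) % 3 != 0:
                continue
            if end - start + 1 < 4:
                continue
            if contig.subseq(end - 1, end) == "AG":
                out.append((s, e))
    # prefer: no exon shrinkage, then minimal total slide, then minimal donor
    out.sort(key=lambda t: (t[0] < 0 or t[1] < 0, abs(t[0]) + abs(t[1]),
                            abs(t[0]), abs(t[1])))
    return out


def _junction_score(contig, upstream, downstream, s, e, ref, n_context=8):
    """Alignment score of a candidate junction against the reference.

    Re-translates ``n_context`` codons either side of the candidate splice
    sites (plus the bridged split codon, if any) and locally aligns the
    peptide to the reference residues the two anchors place at the junction.
    The true splice pair reconstitutes the reference exactly; a shifted pair
    garbles the bridged codon(s).
    """
    e1 = upstream.nt_end + s        # last coding base before the intron
    e2 = downstream.nt_start - e    # first coding base after it
    a = max(upstream.nt_start, upstream.nt_end - 3 * n_context + 1)
    b = min(downstream.nt_end, downstream.nt_start + 3 * n_context - 1)
    if e1 < a - 1 or e2 > b + 1:
        return None
    left = contig.subseq(a, e1) if e1 >= a else ""
    right = contig.subseq(e2, b) if e2 <= b else ""
    coding = left + right
    if len(coding) < 3:
        return None
    peptide = translate(coding, record_id="junction")
    q_lo = max(1, upstream.anchor.query_end - n_context - 3)
    q_hi = min(len(ref.seq), downstream.anchor.query_start + n_context + 3)
    if q_hi < q_lo:
        return None
    window = ProteinSeq("ref_window", ref.seq[q_lo - 1 : q_hi],
                        is_raw_frame=True)
    if not peptide.seq or not window.seq:
        return None
    return pairwise.align_local(peptide, window).score


def infer_intron(
    contig: GenomicContig,
    upstream: CodingSegment,
    downstream: CodingSegment,
    refine_splice: bool = False,
    slide_max: int = DEFAULT_SLIDE_MAX,
    upstream_coding_nt: Optional[int] = None,
    ref: Optional[ProteinSeq] = None,
) -> IntronCall:
    """Call the intron between two anchored segments.

    By default the intron is the entire inter-segment gap. With
    ``refine_splice`` the boundaries may slide by up to ``slide_max`` nt to
    hit a canonical GT...AG pair, re-assigning the slid bases between exon
    and intron without changing the total coding length mod 3.

    ``upstream_coding_nt`` is the number of coding nucleotides upstream of
    the default intron start (from the model's coding start through
    ``upstream.nt_end``); it defaults to the upstream segment alone. The
    phase is this count, corrected for any boundary slide, mod 3.
    """
    gap_length, frame_offset = gap_frame_shift(upstream, downstream)
    if gap_length == 0:
        raise ValueError("no gap between segments: nothing to call an intron in")
    g_lo = upstream.nt_end + 1
    g_hi = downstream.nt_start - 1
    s_slide = 0
    splice = False
    if refine_splice:
        cands = _splice_candidates(contig, g_lo, g_hi, slide_max)
        if (len(cands) > 1 and ref is not None
                and upstream.anchor is not None
                and downstream.anchor is not None):
            scored = []
            for rank, (s, e) in enumerate(cands):
                sc = _junction_score(contig, upstream, downstream, s, e, ref)
                if sc is not None:
                    scored.append((-sc, rank, (s, e)))
            if scored:
                scored.sort()
                cands = [scored[0][2]]
        if cands:
            s_slide, e_slide = cands[0]
            g_lo += s_slide
            g_hi -= e_slide
            splice = True
    elif (g_hi - g_lo + 1 >= 4
          and contig.subseq(g_lo, g_lo + 1) == "GT"
          and contig.subseq(g_hi - 1, g_hi) == "AG"):
        splice = True
    if upstream_coding_nt is None:
        upstream_coding_nt = upstream.nt_end - upstream.nt_start + 1
    phase = (upstream_coding_nt + s_slide) % 3
    evidence = set()
    if frame_offset != 0:
        evidence.add("frame_shift")
    if splice:
        evidence.add("splice_motif")
    return IntronCall(
        nt_start=g_lo,
        nt_end=g_hi,
        phase=phase,
        evidence=evidence,
        donor=contig.subseq(g_lo, min(g_lo + 1, len(contig.seq))),
        acceptor=contig.subseq(max(g_hi - 1, 1), g_hi),
    )


def enumerate_start_codons(
    contig: GenomicContig,
    search_start: int,
    search_end: int,
    frame_anchor: Optional[CodingSegment] = None,
) -> list[StartCodon]:
    """All ATG triplets inside a window, flagged for frame agreement.

    A candidate is ``in_frame`` when it shares the anchor segment's reading
    frame assuming no intervening intron, i.e. (anchor start - ATG start) is
    a multiple of 3.
    """
    if not (1 <= search_start <= search_end <= len(contig.seq)):
        raise ValueError(
            f"window {search_start}..{search_end} outside contig "
            f"(length {len(contig.seq)})"
        )
    out = []
    for pos in range(search_start, search_end - 1):
        if contig.subseq(pos, pos + 2) == "ATG":
            in_frame = False
            if frame_anchor is not None:
                in_frame = (frame_anchor.nt_start - pos) % 3 == 0
            out.append(StartCodon(pos, pos + 2, in_frame))
    return out


def _first_inframe_stop(contig, from_pos, limit):
    """Genomic start of the first stop codon at from_pos, from_pos+3, ..."""
    pos = from_pos
    end = min(len(contig.seq) - 2, from_pos + limit)
    while pos <= end:
        if contig.subseq(pos, pos + 2) in STOP_CODONS:
            return pos
        pos += 3
    return None


def assemble_gene_model(
    contig: GenomicContig,
    segments: Sequence[CodingSegment],
    introns: Sequence[IntronCall],
    starts: Sequence[StartCodon] = (),
    stop_scan: bool = True,
    stop_scan_limit: int = DEFAULT_STOP_SCAN_LIMIT,
) -> GeneModel:
    """Assemble exons, CDS and predicted protein from segments and introns.

    Exon boundaries between consecutive segments are taken from the intron
    calls (which may have refined the raw anchor boundaries). The first exon
    extends upstream to an in-frame start codon reachable without an
    intervening stop; the last exon extends to the first in-frame stop when
    ``stop_scan`` is set. With several viable starts, the most upstream one
    is used for the CDS and the N-terminus is flagged ambiguous.
    """
    if not segments:
        raise ValueError("no segments to assemble")
    segs = sorted(segments, key=lambda s: s.nt_start)
    if any(s.strand != "+" for s in segs):
        raise ValueError(
            "assemble_gene_model works in gene-forward space; flip "
            "reverse-strand inputs with flip_to_forward() first"
        )
    if len(introns) != len(segs) - 1:
        raise ValueError(
            f"{len(segs)} segments need {len(segs) - 1} introns, "
            f"got {len(introns)}"
        )
    introns = [
        replace(i, evidence=set(i.evidence))
        for i in sorted(introns, key=lambda i: i.nt_start)
    ]
    notes: list[str] = []

    exons = []
    for k, seg in enumerate(segs):
        start = segs[0].nt_start if k == 0 else introns[k - 1].nt_end + 1
        end = seg.nt_end if k == len(segs) - 1 else introns[k].nt_start - 1
        if start > end:
            raise ValueError(f"intron boundaries collapse exon {k + 1}")
        exons.append((start, end))

    # --- N-terminus -------------------------------------------------------
    viable = []
    for st in starts:
        if not st.in_frame or st.nt_start >= exons[0][0]:
            continue
        stop = _first_inframe_stop(contig, st.nt_start,
                                   exons[0][0] - st.nt_start)
        if stop is not None and stop < exons[0][0]:
            continue  # in-frame stop between candidate ATG and first exon
        viable.append(st)
    own_start = (
        exons[0][1] - exons[0][0] + 1 >= 3
        and contig.subseq(exons[0][0], exons[0][0] + 2) == "ATG"
    )
    n_terminus_missing = not (viable or own_start)
    n_terminus_ambiguous = False
    if own_start:
        # the anchored homology already reaches a methionine codon; keep it
        if viable:
            notes.append(
                "upstream in-frame start codon(s) also possible: "
                + ", ".join(f"{s.nt_start}-{s.nt_end}" for s in viable)
            )
    elif viable:
        n_terminus_ambiguous = len(viable) > 1
        chosen = min(viable, key=lambda s: s.nt_start)
        exons[0] = (chosen.nt_start, exons[0][1])
        if n_terminus_ambiguous:
            notes.append(
                "multiple in-frame start codons: "
                + ", ".join(f"{s.nt_start}-{s.nt_end}" for s in viable)
            )

    # --- C-terminus -------------------------------------------------------
    c_terminus_missing = True
    if stop_scan:
        cds_len = sum(e - s + 1 for s, e in exons)
        remainder = cds_len % 3  # bases of a codon split across the exon end
        stop = _first_inframe_stop(
            contig, exons[-1][1] + 1 - remainder, stop_scan_limit
        )
        if stop is not None:
            if stop > exons[-1][1] + 1:
                notes.append(
                    f"C-terminus completed to nucleotide {stop - 1} "
                    f"(stop codon at {stop}-{stop + 2})"
                )
            exons[-1] = (exons[-1][0], stop - 1)
            c_terminus_missing = False

    # final phase bookkeeping from the assembled exon chain
    coding = 0
    for k in range(len(exons) - 1):
        coding += exons[k][1] - exons[k][0] + 1
        introns[k].phase = coding % 3

    cds = "".join(contig.subseq(s, e) for s, e in exons)
    prot_raw = translate(cds).seq
    star = prot_raw[:-1].find("*") if prot_raw else -1
    if star != -1:
        coord = _cds_offset_to_genomic(exons, star * 3)
        in_segment = any(s.nt_start <= coord <= s.nt_end for s in segs)
        where = "inside an anchored segment" if in_segment else "in the assembly"
        raise ValueError(
            f"internal stop codon at genomic position {coord} {where}"
        )
    protein = ProteinSeq(
        f"{contig.id}|model",
        prot_raw,
        is_partial=n_terminus_missing or c_terminus_missing,
    )
    return GeneModel(
        contig_id=contig.id,
        strand="+",
        exons=exons,
        introns=list(introns),
        start_candidates=list(starts),
        cds=cds,
        protein=protein,
        n_terminus_missing=n_terminus_missing,
        c_terminus_missing=c_terminus_missing,
        n_terminus_ambiguous=n_terminus_ambiguous,
        notes=notes,
    )


def _cds_offset_to_genomic(exons, offset):
    """Map a 0-based CDS offset to its 1-based genomic coordinate."""
    for s, e in exons:
        n = e - s + 1
        if offset < n:
            return s + offset
        offset -= n
    raise ValueError("CDS offset beyond exon chain")


def flip_to_forward(segment: CodingSegment, contig_len: int) -> CodingSegment:
    """Re-express a reverse-strand segment in reverse-complement coordinates.

    After flipping the contig with reverse_complement(), the returned
    segment is forward-strand in the flipped coordinate system, so the
    assembly machinery applies unchanged.
    """
    if segment.strand != "-":
        raise ValueError("flip_to_forward expects a reverse-strand segment")
    return CodingSegment(
        contig_id=segment.contig_id,
        strand="+",
        frame=abs(segment.frame),
        nt_start=contig_len - segment.nt_end + 1,
        nt_end=contig_len - segment.nt_start + 1,
        peptide=segment.peptide,
        anchor=segment.anchor,
    )


def merge_partial_proteins(
    a: ProteinSeq, b: ProteinSeq, min_overlap: int = 3
) -> ProteinSeq:
    """Merge two partial proteins, a upstream of b.

    The longest exact suffix(a)/prefix(b) overlap of at least ``min_overlap``
    residues is spliced; a near-perfect overlap with mismatches raises
    MergeConflictError; fragments with no detectable overlap are concatenated
    with the junction position recorded in the result metadata.
    """
    max_k = min(len(a.seq), len(b.seq))
    best_near = None
    for k in range(max_k, min_overlap - 1, -1):
        matches = sum(1 for x, y in zip(a.seq[-k:], b.seq[:k]) if x == y)
        if matches == k:
            return ProteinSeq(
                f"{a.id}+{b.id}",
                a.seq + b.seq[k:],
                is_partial=a.is_partial or b.is_partial,
                meta={"overlap": k, "junction": len(a.seq) - k},
            )
        if best_near is None and matches / k >= 0.8:
            best_near = (k, k - matches)
    if best_near is not None:
        k, n_bad = best_near
        raise MergeConflictError(
            f"{n_bad} conflicting residue(s) in a {k}-residue overlap of "
            f"{a.id!r} and {b.id!r}"
        )
    return ProteinSeq(
        f"{a.id}+{b.id}",
        a.seq + b.seq,
        is_partial=a.is_partial or b.is_partial,
        meta={"overlap": 0, "junction": len(a.seq)},
    )


def _protein_pos_to_column(aln_row: str, row_start: int, pos: int):
    """Alignment column (0-based) holding 1-based residue ``pos`` of a row."""
    if pos < row_start:
        return None
    count = row_start - 1
    for col, c in enumerate(aln_row):
        if c != "-":
            count += 1
            if count == pos:
                return col
    return None


def model_intron_protein_positions(model: GeneModel) -> list[tuple[int, int]]:
    """(residue position, phase) of each intron in the model's protein.

    The position is the residue whose codon the intron interrupts (phase
    1/2), or the residue just before the boundary (phase 0).
    """
    out = []
    coding = 0
    exon_iter = iter(model.exons)
    s, e = next(exon_iter)
    for intron in model.introns:
        while e < intron.nt_start:
            coding += e - s + 1
            s, e = next(exon_iter)
        coding_here = coding + (intron.nt_start - s)
        phase = coding_here % 3
        pos = coding_here // 3 + (1 if phase else 0)
        out.append((pos, phase))
    return out


def compare_homolog_introns(
    model: GeneModel,
    homolog_introns: Sequence[tuple[int, int]],
    alignment: pairwise.AlignmentResult,
    tol: int = 2,
) -> list[IntronSupport]:
    """Check each model intron against homolog exon boundaries.

    ``homolog_introns`` are (residue position in the homolog, phase) pairs;
    ``alignment`` maps the model protein (query) to the homolog (subject).
    A model intron is supported when a homolog intron of equal phase lies
    within ``tol`` aligned columns; supported introns gain the
    ``homolog_boundary`` evidence tag.
    """
    hom_cols = [
        (_protein_pos_to_column(alignment.subject_aln,
                                alignment.subject_start, pos), phase)
        for pos, phase in homolog_introns
    ]
    out = []
    for idx, (pos, phase) in enumerate(model_intron_protein_positions(model)):
        col = _protein_pos_to_column(alignment.query_aln,
                                     alignment.query_start, pos)
        if col is None:
            out.append(IntronSupport(idx, False, note="outside alignment span"))
            continue
        best = None
        for h_idx, (h_col, h_phase) in enumerate(hom_cols):
            if h_col is None or h_phase != phase:
                continue
            dist = abs(h_col - col)
            if dist <= tol and (best is None or dist < best[1]):
                best = (h_idx, dist)
        if best is None:
            out.append(IntronSupport(idx, False))
        else:
            model.introns[idx].evidence.add("homolog_boundary")
            out.append(IntronSupport(idx, True, best[0], best[1]))
    return out


def assess_upstream_exon(
    model: GeneModel,
    homolog_introns: Sequence[tuple[int, int]],
    alignment: pairwise.AlignmentResult,
    tol: int = 2,
) -> bool:
    """Hypothesize an extra upstream exon for a model with a missing N-terminus.

    When no in-frame start codon was found, an additional 5' exon is
    plausible if a homolog has an exon boundary where the model protein
    begins. If a homolog intron lies within ``tol`` aligned columns of the
    model's first residue, the hypothesis flag is set (raising the
    hypothesized exon count by one) and True is returned.
    """
    if not model.n_terminus_missing:
        return False
    col = _protein_pos_to_column(alignment.query_aln, alignment.query_start, 1)
    if col is None:
        col = 0  # model residue 1 precedes the alignment: its column is 0
    for pos, _phase in homolog_introns:
        h_col = _protein_pos_to_column(
            alignment.subject_aln, alignment.subject_start, pos
        )
        if h_col is not None and abs(h_col - col) <= tol:
            model.extra_upstream_exon_hypothesized = True
            model.notes.append(
                "missing N-terminus coincides with a homolog exon boundary: "
                "an additional upstream exon is hypothesized"
            )
            return True
    return False


# ---------------------------------------------------------------------------
# GFF3 export
# ---------------------------------------------------------------------------

def gene_model_to_gff3(model: GeneModel, gene_id: str = "gene1") -> str:
    """GFF3 (1-based inclusive) with gene/mRNA/exon/CDS features."""
    lines = ["##gff-version 3"]
    g_start = model.exons[0][0]
    g_end = model.exons[-1][1]
    src = "p25scan"
    strand = model.strand
    lines.append(
        f"{model.contig_id}\t{src}\tgene\t{g_start}\t{g_end}\t.\t{strand}\t."
        f"\tID={gene_id}"
    )
    lines.append(
        f"{model.contig_id}\t{src}\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t."
        f"\tID={gene_id}.t1;Parent={gene_id}"
    )
    coding = 0
    for k, (s, e) in enumerate(model.exons, 1):
        lines.append(
            f"{model.contig_id}\t{src}\texon\t{s}\t{e}\t.\t{strand}\t."
            f"\tID={gene_id}.t1.exon{k};Parent={gene_id}.t1"
        )
        gff_phase = (3 - coding % 3) % 3
        lines.append(
            f"{model.contig_id}\t{src}\tCDS\t{s}\t{e}\t.\t{strand}\t{gff_phase}"
            f"\tID={gene_id}.t1.cds;Parent={gene_id}.t1"
        )
        coding += e - s + 1
    return "\n".join(lines) + "\n"
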