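"""End-to-end orchestration: anchor -> gene model -> merge -> classify -> tree.

This is the library behind the ``p25scan run`` subcommand. Every stage is a
plain function from the sibling modules; this module only wires them,
normalizes reverse-strand genes into gene-forward space and back, and
serializes results deterministically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import domains as _domains
from . import genemodel as _gm
from . import pairwise as _pw
from . import phylo_lite as _phylo
from .seqio import (
    GenomicContig, ProteinSeq, reverse_complement, write_fasta,
    write_newick,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


# splice-search radius: anchors can drift a few codons into intron sequence
# (or fall short by a few), so the GT...AG search must reach past that —
# four codons plus split-codon bases = 14 nt, rounded up
DEFAULT_REFINE_RADIUS = 15


def _rebuild_segment(seg, cols, mat):
    """Rebuild a (forward-strand) segment from a subset of anchor columns.

    ``cols`` is a contiguous run of (q_char, s_char, q_pos, s_pos) tuples;
    boundary gap columns are stripped. Returns None if nothing remains.
    """
    lo, hi = 0, len(cols)
    while lo < hi and ("-" in (cols[lo][0], cols[lo][1])):
        lo += 1
    while hi > lo and ("-" in (cols[hi - 1][0], cols[hi - 1][1])):
        hi -= 1
    cols = cols[lo:hi]
    if not cols:
        return None
    qa = "".join(c[0] for c in cols)
    sa = "".join(c[1] for c in cols)
    s_positions = [c[3] for c in cols if c[1] != "-"]
    q_positions = [c[2] for c in cols if c[0] != "-"]
    old = seg.anchor
    shift = (s_positions[0] - old.subject_start) * 3
    shrink = (old.subject_end - s_positions[-1]) * 3
    n_id = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
    score = _pw._score_block(qa, sa, mat, _pw.DEFAULT_GAP_OPEN,
                             _pw.DEFAULT_GAP_EXTEND)
    anchor = _pw.AlignmentResult(
        query_id=old.query_id, subject_id=old.subject_id,
        query_start=q_positions[0], query_end=q_positions[-1],
        subject_start=s_positions[0], subject_end=s_positions[-1],
        score=score, n_identical=n_id, n_columns=len(qa),
        percent_identity=_pw._round_half_up(100.0 * n_id / len(qa), 2),
        query_cover=old.query_cover, query_aln=qa, subject_aln=sa,
    )
    return _gm.CodingSegment(
        contig_id=seg.contig_id, strand=seg.strand, frame=seg.frame,
        nt_start=seg.nt_start + shift, nt_end=seg.nt_end - shrink,
        peptide=sa.replace("-", ""), anchor=anchor,
    )


def _anchor_columns(seg):
    """(q_char, s_char, q_pos, s_pos) per column of a segment's anchor."""
    out = []
    q = seg.anchor.query_start - 1
    s = seg.anchor.subject_start - 1
    for a, b in zip(seg.anchor.query_aln, seg.anchor.subject_aln):
        if a != "-":
            q += 1
        if b != "-":
            s += 1
        out.append((a, b, q, s))
    return out


def resolve_query_overlaps(chain: list, mat=None) -> list:
    """Make adjacent segments' reference claims disjoint.

    Every reference residue is encoded by exactly one exon, so when the
    anchor of one exon block drifts into intron sequence it fuzzily re-claims
    residues that belong to its neighbour; the overlapping columns are
    removed from whichever side scores them worse.
    """
    if mat is None:
        mat = _pw.get_matrix(_pw.DEFAULT_MATRIX)
    chain = list(chain)
    k = 0
    while k < len(chain) - 1:
        a, b = chain[k], chain[k + 1]
        if a.anchor.query_end < b.anchor.query_start:
            k += 1
            continue
        a_cols = _anchor_columns(a)
        b_cols = _anchor_columns(b)
        a_over = [c for c in a_cols if c[2] >= b.anchor.query_start
                  and c[0] != "-"]
        b_over = [c for c in b_cols if c[2] <= a.anchor.query_end
                  and c[0] != "-"]
        score = lambda cols: sum(
            mat.pair_score(c[0], c[1]) for c in cols if c[1] != "-"
        )
        if score(a_over) < score(b_over):
            keep = [c for c in a_cols if c[2] < b.anchor.query_start]
            new = _rebuild_segment(a, keep, mat)
            if new is None:
                del chain[k]
                k = max(k - 1, 0)
                continue
            chain[k] = new
        else:
            keep = [c for c in b_cols if c[2] > a.anchor.query_end]
            new = _rebuild_segment(b, keep, mat)
            if new is None:
                del chain[k + 1]
                continue
            chain[k + 1] = new
        k += 1
    return chain


def select_chain(segments: Sequence[_gm.CodingSegment]) -> list:
    """Best colinear chain of anchored segments (one gene's exon blocks).

    Segments in a chain must be disjoint and ascending on the genome and
    non-decreasing on the reference (local alignments of adjacent exon
    blocks may share a few boundary residues). Among all such chains the
    one with the highest total anchor score is returned; this discards
    spurious secondary hits and frame-shifted shadows of true exons.
    """
    segs = sorted(segments, key=lambda s: (s.nt_start, s.nt_end))
    n = len(segs)
    if n <= 1:
        return segs
    best_score = [0.0] * n
    back: list[Optional[int]] = [None] * n
    for i in range(n):
        best_score[i] = segs[i].anchor.score
        for j in range(i):
            if (segs[j].nt_end < segs[i].nt_start
                    and segs[j].anchor.query_start <= segs[i].anchor.query_start
                    and segs[j].anchor.query_end <= segs[i].anchor.query_end
                    and best_score[j] + segs[i].anchor.score > best_score[i]):
                best_score[i] = best_score[j] + segs[i].anchor.score
                back[i] = j
    end = max(range(n), key=lambda i: best_score[i])
    chain = []
    k: Optional[int] = end
    while k is not None:
        chain.append(segs[k])
        k = back[k]
    chain.reverse()
    return chain


def reconstruct_gene(
    contig: GenomicContig,
    ref: ProteinSeq,
    min_segment_score: float = _pw.DEFAULT_MIN_SEGMENT_SCORE,
    refine_splice: bool = False,
    start_window: int = 300,
    stop_scan: bool = True,
    stop_scan_limit: int = _gm.DEFAULT_STOP_SCAN_LIMIT,
    max_gap_cols: int = _pw.DEFAULT_MAX_GAP_COLS,
    slide_max: int = DEFAULT_REFINE_RADIUS,
):
    """Anchor a reference protein and assemble the gene model.

    Returns (GeneModel, segments). Reverse-strand genes are assembled in
    reverse-complement space and reported back in forward coordinates with
    ``strand == '-'``.
    """
    segments = _pw.anchor_protein_to_genome(
        ref, contig, min_segment_score=min_segment_score,
        max_gap_cols=max_gap_cols,
    )
    if not segments:
        raise PipelineError(
            f"anchor: no segment of {ref.id!r} on {contig.id!r} scores "
            f">= {min_segment_score}"
        )
    best = max(segments, key=lambda s: s.anchor.score)
    segs = [s for s in segments if s.strand == best.strand]
    flipped = best.strand == "-"
    work_contig = contig
    if flipped:
        work_contig = GenomicContig(contig.id, reverse_complement(contig.seq))
        segs = [_gm.flip_to_forward(s, len(contig.seq)) for s in segs]
    segs = resolve_query_overlaps(select_chain(segs))
    if not segs:
        raise PipelineError("anchor: no segments left after chain selection")

    introns = []
    coding = 0
    prev_exon_start = segs[0].nt_start
    for k in range(len(segs) - 1):
        upstream_coding = coding + (segs[k].nt_end - prev_exon_start + 1)
        try:
            intron = _gm.infer_intron(
                work_contig, segs[k], segs[k + 1],
                refine_splice=refine_splice, slide_max=slide_max,
                upstream_coding_nt=upstream_coding, ref=ref,
            )
        except ValueError as exc:
            raise PipelineError(f"genemodel: {exc}") from exc
        introns.append(intron)
        coding += intron.nt_start - prev_exon_start
        prev_exon_start = intron.nt_end + 1

    if segs[0].nt_start > 1 and start_window > 0:
        win_lo = max(1, segs[0].nt_start - start_window)
        starts = _gm.enumerate_start_codons(
            work_contig, win_lo, segs[0].nt_start - 1, frame_anchor=segs[0]
        ) if segs[0].nt_start - 1 >= win_lo else []
    else:
        starts = []

    try:
        model = _gm.assemble_gene_model(
            work_contig, segs, introns, starts,
            stop_scan=stop_scan, stop_scan_limit=stop_scan_limit,
        )
    except ValueError as exc:
        raise PipelineError(f"genemodel: {exc}") from exc
    if flipped:
        model = _flip_model(model, len(contig.seq))
    return model, segments


def _flip_model(model: _gm.GeneModel, L: int) -> _gm.GeneModel:
    """Map a model assembled in reverse-complement space back to forward."""
    model.strand = "-"
    model.exons = sorted((L - e + 1, L - s + 1) for s, e in model.exons)
    for intr in model.introns:
        intr.nt_start, intr.nt_end = L - intr.nt_end + 1, L - intr.nt_start + 1
    model.introns.sort(key=lambda i: i.nt_start)
    for st in model.start_candidates:
        st.nt_start, st.nt_end = L - st.nt_end + 1, L - st.nt_start + 1
    return model


def pairwise_distance_matrix(proteins: Sequence[ProteinSeq]) -> _phylo.DistanceMatrix:
    """Mismatch fraction over global-alignment columns, for the sanity tree."""
    n = len(proteins)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = _pw.align_global(proteins[i], proteins[j])
            d[i, j] = d[j, i] = 1.0 - res.n_identical / res.n_columns
    return _phylo.DistanceMatrix([p.id for p in proteins], d)


def intron_to_dict(i: _gm.IntronCall) -> dict:
    return {
        "nt_start": i.nt_start,
        "nt_end": i.nt_end,
        "length": i.length,
        "phase": i.phase,
        "evidence": sorted(i.evidence),
        "donor": i.donor,
        "acceptor": i.acceptor,
    }


def model_to_dict(model: _gm.GeneModel) -> dict:
    return {
        "contig_id": model.contig_id,
        "strand": model.strand,
        "exons": [list(e) for e in model.exons],
        "introns": [intron_to_dict(i) for i in model.introns],
        "start_candidates": [
            {"nt_start": s.nt_start, "nt_end": s.nt_end, "in_frame": s.in_frame}
            for s in model.start_candidates
        ],
        "cds_length": len(model.cds),
        "protein": model.protein.seq,
        "n_terminus_missing": model.n_terminus_missing,
        "c_terminus_missing": model.c_terminus_missing,
        "n_terminus_ambiguous": model.n_terminus_ambiguous,
        "n_exons_supported": model.n_exons_supported,
        "n_exons_hypothesized": model.n_exons_hypothesized,
        "notes": list(model.notes),
    }


def domain_to_dict(d: _domains.DomainAnnotation) -> dict:
    out = {
        "kind": d.kind,
        "start": d.start,
        "end": d.end,
        "rossmann_absent": d.rossmann_absent,
    }
    for name, hit in (("start_motif", d.start_motif), ("rossmann", d.rossmann)):
        out[name] = (
            {"start": hit.start, "end": hit.end, "matched": hit.matched}
            if hit else None
        )
    return out


def run_pipeline(config: dict) -> dict:
    """Run the full workflow and write artifacts under ``out_dir``.

    Required config keys: ``contig`` (path), ``ref`` (path), ``out_dir``.
    Optional: ``merge_with`` (path to a downstream partial protein),
    ``refine_splice``, ``min_segment_score``, ``min_overlap``, thresholds of
    the stage functions. Returns the summary dict (also written as JSON).
    """
    from .seqio import read_fasta
    from .genemodel import gene_model_to_gff3, merge_partial_proteins

    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    contigs = [r for r in read_fasta(config["contig"], kind="dna")]
    refs = [r for r in read_fasta(config["ref"], kind="protein")]
    if not contigs:
        raise PipelineError("input: contig FASTA is empty")
    contig = contigs[0]
    if not contig.seq:
        raise PipelineError("input: empty contig sequence")
    ref = ProteinSeq(refs[0].id, refs[0].seq, is_raw_frame=False)

    model, segments = reconstruct_gene(
        contig, ref,
        min_segment_score=float(config.get("min_segment_score",
                                           _pw.DEFAULT_MIN_SEGMENT_SCORE)),
        refine_splice=bool(config.get("refine_splice", False)),
        start_window=int(config.get("start_window", 300)),
        stop_scan=bool(config.get("stop_scan", True)),
        stop_scan_limit=int(config.get("stop_scan_limit",
                                       _gm.DEFAULT_STOP_SCAN_LIMIT)),
        max_gap_cols=int(config.get("max_gap_cols", _pw.DEFAULT_MAX_GAP_COLS)),
        slide_max=int(config.get("slide_max", DEFAULT_REFINE_RADIUS)),
    )

    final_protein = model.protein
    merge_meta = None
    if config.get("merge_with"):
        downstream = read_fasta(config["merge_with"], kind="protein")[0]
        downstream = ProteinSeq(downstream.id, downstream.seq, is_partial=True)
        merged = merge_partial_proteins(
            final_protein, downstream,
            min_overlap=int(config.get("min_overlap", 3)),
        )
        merge_meta = dict(merged.meta)
        final_protein = merged

    doms = _domains.annotate_p25alpha(final_protein)
    call = _domains.classify_architecture(doms)

    tree_path = None
    pool = [final_protein] + [
        ProteinSeq(r.id, r.seq) for r in refs[1:]
    ]
    if len(pool) >= 3:
        dm = pairwise_distance_matrix(pool)
        tree = _phylo.neighbor_joining(dm)
        tree_path = out_dir / "tree.nwk"
        write_newick(tree, tree_path)

    write_fasta([final_protein], out_dir / "protein.faa")
    (out_dir / "model.gff3").write_text(gene_model_to_gff3(model))
    seg_tsv = out_dir / "segments.tsv"
    with open(seg_tsv, "w") as fh:
        fh.write("ref_id\tcontig_id\tstrand\tframe\tnt_start\tnt_end\t"
                 "pct_id\tscore\tpeptide\n")
        for s in segments:
            fh.write(
                f"{s.anchor.query_id}\t{s.contig_id}\t{s.strand}\t{s.frame}\t"
                f"{s.nt_start}\t{s.nt_end}\t{s.anchor.percent_identity:.2f}\t"
                f"{s.anchor.score:g}\t{s.peptide}\n"
            )

    summary = {
        "parameters": {
            k: config.get(k, default)
            for k, default in (
                ("min_segment_score", _pw.DEFAULT_MIN_SEGMENT_SCORE),
                ("refine_splice", False),
                ("start_window", 300),
                ("stop_scan", True),
                ("stop_scan_limit", _gm.DEFAULT_STOP_SCAN_LIMIT),
                ("max_gap_cols", _pw.DEFAULT_MAX_GAP_COLS),
                ("slide_max", DEFAULT_REFINE_RADIUS),
                ("min_overlap", 3),
                ("seed", 0),
            )
        },
        "gene_model": model_to_dict(model),
        "merge": merge_meta,
        "final_protein": {"id": final_protein.id, "seq": final_protein.seq},
        "domains": [domain_to_dict(d) for d in doms],
        "architecture": call.label,
        "tree": str(tree_path) if tree_path else None,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
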