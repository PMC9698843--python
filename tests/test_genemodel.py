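import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from p25scan import (
    CodingSegment, GenomicContig, ProteinSeq,
    align_global, assemble_gene_model, assess_upstream_exon,
    compare_homolog_introns, enumerate_start_codons, gap_frame_shift,
    gene_model_to_gff3, infer_intron, make_fungal_type_protein, make_gene,
    merge_partial_proteins, mutate_homolog, reconstruct_gene,
    SyntheticGeneSpec,
)
from p25scan.genemodel import MergeConflictError, model_intron_protein_positions


def seg(start, end, contig_id="c", strand="+", frame=1, peptide=None):
    n_aa = (end - start + 1) // 3
    return CodingSegment(contig_id, strand, frame, start, end,
                         peptide or "A" * n_aa)


class TestGapFrameShift:
    def test_printed_anchored_block_coordinates(self):
        # blocks ending at 1733 and starting at 1960: a 226-nt gap whose
        # length is not divisible by 3, hence a phase shift
        gap, offset = gap_frame_shift(seg(1683, 1733), seg(1960, 2037))
        assert gap == 226
        assert offset == 1

    def test_adjacent_segments(self):
        assert gap_frame_shift(seg(1, 9), seg(10, 18)) == (0, 0)

    def test_out_of_order_rejected(self):
        with pytest.raises(ValueError):
            gap_frame_shift(seg(100, 150), seg(90, 98))

    @given(st.integers(1, 10_000), st.integers(1, 300), st.integers(0, 500),
           st.integers(1, 300))
    def test_matches_direct_arithmetic(self, a, la, gap, lb):
        up_end = a + 3 * la - 1
        down_start = up_end + 1 + gap
        g, off = gap_frame_shift(
            seg(a, up_end), seg(down_start, down_start + 3 * lb - 1)
        )
        assert g == gap and off == gap % 3


def _fig2_like_contig(rng):
    """A contig mimicking the published coordinate layout: anchored blocks
    at 1683-1733 and 1960-2037 with ATG candidates at 1505 and 1511."""
    seq = list("".join(rng.choice(list("ACGT"), size=2400)))
    # scrub ATGs from the search window, then plant the two candidates
    window = "".join(seq[1449:1560])
    for k in range(len(window) - 2):
        if window[k:k + 3] == "ATG":
            seq[1449 + k] = "C"
    seq[1504:1507] = "ATG"
    seq[1510:1513] = "ATG"
    return GenomicContig("contig_like_fig2", "".join(seq))


class TestInferIntron:
    def test_frame_shift_gap_called_as_intron(self, rng):
        contig = _fig2_like_contig(rng)
        intron = infer_intron(contig, seg(1683, 1733), seg(1960, 2037))
        assert (intron.nt_start, intron.nt_end) == (1734, 1959)
        assert intron.length == 226
        assert "frame_shift" in intron.evidence

    def test_mod3_gap_lacks_frame_shift_evidence(self, rng):
        contig = _fig2_like_contig(rng)
        intron = infer_intron(contig, seg(1683, 1733), seg(1959, 2036))
        assert intron.length == 225  # whole gap 1734..1958, divisible by 3
        assert "frame_shift" not in intron.evidence

    def test_zero_gap_rejected(self, rng):
        contig = _fig2_like_contig(rng)
        with pytest.raises(ValueError):
            infer_intron(contig, seg(1, 9), seg(10, 18))

    def test_planted_phases_recovered(self):
        recovered = []
        for seed in range(40):
            phases = [int(x) for x in
                      np.random.default_rng(seed).integers(0, 3, size=2)]
            prot, _ = make_fungal_type_protein(seed=seed)
            truth = make_gene(SyntheticGeneSpec(
                protein=prot, n_exons=3, intron_lengths=[75, 91],
                intron_phases=phases, seed=seed,
            ))
            model, _ = reconstruct_gene(truth.contig, truth.protein,
                                        refine_splice=True)
            recovered.append(
                [i.phase for i in model.introns] == phases
            )
        assert all(recovered)


class TestStartCodons:
    def test_window_without_atg_is_empty(self, rng):
        contig = _fig2_like_contig(rng)
        assert enumerate_start_codons(contig, 1520, 1560) == [] or all(
            c.nt_start > 1513 for c in
            enumerate_start_codons(contig, 1520, 1560)
        )

    def test_published_window_has_the_two_candidates(self, rng):
        contig = _fig2_like_contig(rng)
        cands = enumerate_start_codons(contig, 1450, 1560,
                                       frame_anchor=seg(1683, 1733))
        assert [c.nt_start for c in cands] == [1505, 1511]
        # neither is in frame with the anchored block without an intron:
        # (1683-1505) % 3 == (1683-1511) % 3 == 1
        assert all(not c.in_frame for c in cands)

    def test_invalid_window(self, rng):
        contig = _fig2_like_contig(rng)
        with pytest.raises(ValueError):
            enumerate_start_codons(contig, 0, 50)


class TestAssemble:
    def test_single_exon_gene_exact(self):
        prot, _ = make_fungal_type_protein(seed=11)
        truth = make_gene(SyntheticGeneSpec(
            protein=prot, n_exons=1, intron_lengths=[], intron_phases=[],
            seed=11,
        ))
        model, _ = reconstruct_gene(truth.contig, truth.protein)
        assert list(model.exons) == truth.exons
        assert model.cds == truth.cds
        assert model.protein.seq == truth.protein.seq
        assert not model.n_terminus_missing
        assert not model.c_terminus_missing

    def test_four_exon_phase111_gene(self):
        prot, _ = make_fungal_type_protein(seed=12)
        truth = make_gene(SyntheticGeneSpec(
            protein=prot, n_exons=4, intron_lengths=[90, 110, 70],
            intron_phases=[1, 1, 1], seed=12,
        ))
        model, _ = reconstruct_gene(truth.contig, truth.protein,
                                    refine_splice=True)
        assert model.n_exons_supported == 4
        assert model.protein.seq == truth.protein.seq
        assert [i.phase for i in model.introns] == [1, 1, 1]

    def test_stop_completion_and_missing_terminus_flags(self):
        # downstream fragment whose last codon is followed by a stop:
        # the C-terminus completes; the N-terminus (no ATG) stays missing
        prot, _ = make_fungal_type_protein(seed=13)
        truth = make_gene(SyntheticGeneSpec(
            protein=prot, n_exons=1, intron_lengths=[], intron_phases=[],
            include_start=False, include_stop=True, seed=13,
        ))
        ref = ProteinSeq("ref", truth.protein.seq)
        model, _ = reconstruct_gene(truth.contig, ref, start_window=0)
        assert not model.c_terminus_missing
        assert model.n_terminus_missing or model.protein.seq[0] == "M"

    def test_internal_stop_inside_segment_is_hard_error(self):
        contig = GenomicContig("c", "ATGAAATAAAAATGA")
        s = seg(1, 15, peptide="MK*KX")
        with pytest.raises(ValueError, match="stop"):
            assemble_gene_model(contig, [s], [], stop_scan=False)

    def test_exon_lengths_and_intron_phase_bookkeeping(self):
        for seed in (21, 22, 23):
            prot, _ = make_fungal_type_protein(seed=seed)
            truth = make_gene(SyntheticGeneSpec(
                protein=prot, n_exons=4, intron_lengths=[61, 80, 99],
                intron_phases=[2, 1, 0], seed=seed,
            ))
            model, _ = reconstruct_gene(truth.contig, truth.protein,
                                        refine_splice=True)
            total = sum(e - s + 1 for s, e in model.exons)
            assert total % 3 == 0
            coding = 0
            for k, (s, e) in enumerate(model.exons[:-1]):
                coding += e - s + 1
                assert model.introns[k].phase == coding % 3
            # removing intron nucleotides reproduces the CDS
            spliced = "".join(
                truth.contig.subseq(s, e) for s, e in model.exons
            )
            assert spliced == model.cds

    def test_gff3_export_is_wellformed(self):
        prot, _ = make_fungal_type_protein(seed=14)
        truth = make_gene(SyntheticGeneSpec(
            protein=prot, n_exons=2, intron_lengths=[70], intron_phases=[1],
            seed=14,
        ))
        model, _ = reconstruct_gene(truth.contig, truth.protein,
                                    refine_splice=True)
        gff = gene_model_to_gff3(model)
        lines = [l for l in gff.splitlines() if not l.startswith("#")]
        kinds = [l.split("\t")[2] for l in lines]
        assert kinds == ["gene", "mRNA", "exon", "CDS", "exon", "CDS"]
        for l in lines:
            f = l.split("\t")
            assert int(f[3]) <= int(f[4])


class TestMerge:
    def test_exact_overlap_splice(self):
        a = ProteinSeq("a", "MKLV", is_partial=True)
        b = ProteinSeq("b", "LVGD", is_partial=True)
        merged = merge_partial_proteins(a, b, min_overlap=2)
        assert merged.seq == "MKLVGD"
        assert merged.meta["overlap"] == 2

    def test_disjoint_fragments_concatenated_with_junction(self):
        a = ProteinSeq("a", "MKWWEDY")
        b = ProteinSeq("b", "HHRRTTG")
        merged = merge_partial_proteins(a, b)
        assert merged.seq == a.seq + b.seq
        assert merged.meta["overlap"] == 0
        assert merged.meta["junction"] == len(a.seq)

    def test_conflicting_overlap_raises(self):
        a = ProteinSeq("a", "MKLVANDEGH")
        b = ProteinSeq("b", "ANDEGWKLMN")  # 5/6 of the overlap agrees
        with pytest.raises(MergeConflictError):
            merge_partial_proteins(a, b, min_overlap=4)

    def test_random_splits_recover_original(self, rng):
        prot, _ = make_fungal_type_protein(seed=15)
        n = len(prot.seq)
        for _ in range(100):
            i = int(rng.integers(10, n - 20))
            o = int(rng.integers(5, 15))
            a = ProteinSeq("a", prot.seq[: i + o], is_partial=True)
            b = ProteinSeq("b", prot.seq[i:], is_partial=True)
            merged = merge_partial_proteins(a, b, min_overlap=3)
            assert merged.seq == prot.seq
            assert merged.is_partial


class TestHomologIntrons:
    def _model_and_homolog(self, seed, identity=100.0):
        prot, _ = make_fungal_type_protein(seed=seed)
        truth = make_gene(SyntheticGeneSpec(
            protein=prot, n_exons=3, intron_lengths=[81, 96],
            intron_phases=[1, 0], seed=seed,
        ))
        model, _ = reconstruct_gene(truth.contig, truth.protein,
                                    refine_splice=True)
        homolog = (truth.protein if identity == 100.0 else
                   mutate_homolog(truth.protein, identity,
                                  preserve_motifs=True, seed=seed + 500))
        return model, homolog

    def test_exact_boundary_same_phase_supported(self):
        model, homolog = self._model_and_homolog(31)
        positions = model_intron_protein_positions(model)
        aln = align_global(model.protein, homolog)
        support = compare_homolog_introns(model, positions, aln)
        assert all(s.supported for s in support)
        assert all("homolog_boundary" in i.evidence for i in model.introns)

    def test_intronless_homolog_gives_no_support(self):
        model, homolog = self._model_and_homolog(32)
        aln = align_global(model.protein, homolog)
        support = compare_homolog_introns(model, [], aln)
        assert support and not any(s.supported for s in support)

    def test_shared_boundaries_under_divergence(self):
        supported = total = 0
        for seed in range(40):
            model, homolog = self._model_and_homolog(seed, identity=80.0)
            positions = model_intron_protein_positions(model)
            aln = align_global(model.protein, homolog)
            res = compare_homolog_introns(model, positions, aln, tol=2)
            supported += sum(s.supported for s in res)
            total += len(res)
        assert supported / total >= 0.95

    def test_upstream_exon_hypothesis(self):
        prot, _ = make_fungal_type_protein(seed=33)
        truth = make_gene(SyntheticGeneSpec(
            protein=prot, n_exons=1, intron_lengths=[], intron_phases=[],
            include_start=False, seed=33,
        ))
        ref = ProteinSeq("ref", truth.protein.seq)
        model, _ = reconstruct_gene(truth.contig, ref, start_window=0)
        assert model.n_terminus_missing
        base = model.n_exons_supported
        homolog = truth.protein
        aln = align_global(model.protein, homolog)
        # homolog with an exon boundary right where the model protein starts
        assert assess_upstream_exon(model, [(1, 1)], aln)
        assert model.n_exons_hypothesized == base + 1
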