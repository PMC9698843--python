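"""Ground-truth generators for end-to-end testing of the pipeline.

The generator emulates the study system: a multi-exon gene on a genomic
contig whose protein product is a fungal-type TPPP — one complete p25alpha
domain (start signature plus Rossmann-like signature ~160 residues apart)
followed by a partial C-terminal duplicate carrying only the Rossmann
signature — with GT...AG introns of configurable length and phase, and
mutated homologs at a configurable percent identity. Back-translation uses
uniform codon choice; the mutation model is substitution-only so that truth
coordinates stay exact. All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from . import domains as _domains
from .domains import (
    MotifPattern, compile_pattern, START_MOTIF_SPEC, ROSSMANN_SPEC,
)
from .genemodel import IntronCall
from .seqio import GenomicContig, ProteinSeq, translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
_STOPS = sorted(_STANDARD.stop_codons)


@dataclass
class SyntheticGeneSpec:
    """Recipe for a planted gene; invariants checked at generation time."""

    protein: ProteinSeq
    n_exons: int = 4
    intron_lengths: Sequence[int] = ()
    intron_phases: Sequence[int] = ()
    include_start: bool = True
    include_stop: bool = True
    flank_len: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("need at least one exon")
        if len(self.intron_phases) != self.n_exons - 1:
            raise ValueError(
                f"{self.n_exons} exons require {self.n_exons - 1} intron "
                f"phases, got {len(self.intron_phases)}"
            )
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("one intron length per intron required")
        if any(p not in (0, 1, 2) for p in self.intron_phases):
            raise ValueError("phases must be 0, 1 or 2")
        if any(l < 4 for l in self.intron_lengths):
            raise ValueError("introns need >= 4 nt for GT...AG")


@dataclass
class SyntheticTruth:
    contig: GenomicContig
    exons: list  # (nt_start, nt_end) of coding sequence, ascending
    introns: list  # IntronCall with planted phases
    protein: ProteinSeq
    cds: str
    domain_annotations: list = field(default_factory=list)
    architecture_label: str = ""
    start_codon: Optional[tuple] = None  # (nt_start, nt_end)
    stop_codon: Optional[tuple] = None


def _random_protein(rng, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _instantiate_motif(rng, pat: MotifPattern) -> str:
    out = []
    for elem in pat.elements:
        if elem is None:
            out.append(rng.choice(list(AA20)))
        else:
            out.append(sorted(elem)[rng.integers(len(elem))])
    return "".join(out)


def make_fungal_type_protein(
    core_len: int = 160,
    interdomain_len: int = 30,
    seed: int = 0,
    n_term_pad: int = 10,
    c_term_pad: int = 10,
    partial_lead: int = 30,
    l_min: int = _domains.L_MIN,
    l_max: int = _domains.L_MAX,
    protein_id: str = "synthetic_fungal_tppp",
):
    """A synthetic fungal-type TPPP with recorded domain truth.

    Layout: [pad] [start motif ... Rossmann] (complete domain of
    ``core_len`` residues) [interdomain] [lead ... Rossmann] (partial
    duplicate) [pad]. Returns (ProteinSeq, list of truth records), each
    truth record a dict with the domain kind and motif coordinates.
    """
    if not (l_min <= core_len <= l_max):
        raise ValueError(
            f"core_len {core_len} outside the domain window [{l_min}, {l_max}]"
        )
    start_pat = compile_pattern(START_MOTIF_SPEC, "p25alpha_start")
    ross_pat = compile_pattern(ROSSMANN_SPEC, "rossmann_like")
    filler = core_len - start_pat.length - ross_pat.length
    if filler < 0:
        raise ValueError("core_len shorter than the two signatures")
    rng = np.random.default_rng(seed)
    seq = (
        _random_protein(rng, n_term_pad)
        + _instantiate_motif(rng, start_pat)
        + _random_protein(rng, filler)
        + _instantiate_motif(rng, ross_pat)
        + _random_protein(rng, interdomain_len)
        + _random_protein(rng, partial_lead)
        + _instantiate_motif(rng, ross_pat)
        + _random_protein(rng, c_term_pad)
    )
    d1_start = n_term_pad + 1
    d1_end = n_term_pad + core_len
    ross2_start = d1_end + interdomain_len + partial_lead + 1
    truth = [
        {
            "kind": "complete_p25alpha",
            "start_motif": (d1_start, d1_start + start_pat.length - 1),
            "rossmann": (d1_end - ross_pat.length + 1, d1_end),
        },
        {
            "kind": "partial_p25alpha",
            "rossmann": (ross2_start, ross2_start + ross_pat.length - 1),
        },
    ]
    return ProteinSeq(protein_id, seq), truth


def back_translate(protein: str, rng) -> str:
    """Uniform-random codon choice per residue (no codon-usage model)."""
    out = []
    for aa in protein:
        if aa not in _CODONS_FOR:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons = _CODONS_FOR[aa]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _exon_boundaries(cds_len: int, n_exons: int, phases) -> list[int]:
    """Cumulative coding lengths at which introns fall, honoring phases."""
    cuts = []
    prev = 0
    for i, phase in enumerate(phases, start=1):
        target = round(cds_len * i / n_exons)
        c = 3 * (target // 3) + phase
        if c <= prev + 2:
            c = 3 * ((prev + 3) // 3) + phase
            if c <= prev:
                c += 3
        if c >= cds_len:
            raise ValueError(
                "cannot place requested intron phases: coding sequence too "
                "short for the requested exon count"
            )
        cuts.append(c)
        prev = c
    return cuts


def make_gene(spec: SyntheticGeneSpec) -> SyntheticTruth:
    """Plant a gene with known exons, introns and protein on a contig."""
    rng = np.random.default_rng(spec.seed)
    prot = spec.protein.seq
    if spec.include_start and not prot.startswith("M"):
        prot = "M" + prot
    cds = back_translate(prot, rng)
    cuts = _exon_boundaries(len(cds), spec.n_exons, spec.intron_phases)

    exon_dna = []
    prev = 0
    for c in cuts:
        exon_dna.append(cds[prev:c])
        prev = c
    exon_dna.append(cds[prev:])

    intron_dna = []
    for length in spec.intron_lengths:
        core = _random_dna(rng, length - 4)
        intron_dna.append("GT" + core + "AG")

    flank5 = _random_dna(rng, spec.flank_len)
    flank3 = _random_dna(rng, spec.flank_len)
    stop = _STOPS[rng.integers(len(_STOPS))] if spec.include_stop else ""

    parts = [flank5]
    exons = []
    introns = []
    pos = len(flank5)  # 0-based length so far
    coding = 0
    for k, e_dna in enumerate(exon_dna):
        exons.append((pos + 1, pos + len(e_dna)))
        parts.append(e_dna)
        pos += len(e_dna)
        coding += len(e_dna)
        if k < len(intron_dna):
            i_dna = intron_dna[k]
            introns.append(
                IntronCall(
                    nt_start=pos + 1,
                    nt_end=pos + len(i_dna),
                    phase=coding % 3,
                    evidence={"planted"},
                    donor="GT",
                    acceptor="AG",
                )
            )
            parts.append(i_dna)
            pos += len(i_dna)
    parts.append(stop)
    parts.append(flank3)
    contig = GenomicContig("synth_contig", "".join(parts))

    # validate internal consistency
    spliced = "".join(contig.subseq(s, e) for s, e in exons)
    assert spliced == cds
    assert translate(cds).seq == prot
    for intr, phase in zip(introns, spec.intron_phases):
        assert intr.phase == phase

    truth = SyntheticTruth(
        contig=contig,
        exons=exons,
        introns=introns,
        protein=ProteinSeq(spec.protein.id, prot, is_partial=False),
        cds=cds,
        start_codon=(exons[0][0], exons[0][0] + 2) if spec.include_start else None,
        stop_codon=(
            (exons[-1][1] + 1, exons[-1][1] + 3) if spec.include_stop else None
        ),
    )
    return truth


def mutate_homolog(
    p: ProteinSeq,
    target_identity: float,
    preserve_motifs: bool = True,
    seed: int = 0,
    motif_specs: Sequence[str] = (START_MOTIF_SPEC, ROSSMANN_SPEC),
) -> ProteinSeq:
    """Point-substituted copy of ``p`` at a target percent identity.

    Substitutions avoid motif positions when ``preserve_motifs`` is set, so
    degenerate-signature scans still hit the mutated homolog. Deterministic
    per seed; realized identity is within ±2 points of the target.
    """
    if not (0 < target_identity <= 100):
        raise ValueError("target_identity must be in (0, 100]")
    n = len(p.seq)
    k = round(n * (1 - target_identity / 100.0))
    if k == 0:
        return ProteinSeq(f"{p.id}|id{target_identity:g}", p.seq,
                          is_partial=p.is_partial)
    protected: set[int] = set()
    if preserve_motifs:
        from .domains import scan_motif
        for spec_str in motif_specs:
            pat = compile_pattern(spec_str)
            for hit in scan_motif(p, pat):
                protected.update(range(hit.start - 1, hit.end))
    allowed = [i for i in range(n) if i not in protected]
    if k > len(allowed):
        raise ValueError(
            f"target identity {target_identity}% needs {k} substitutions but "
            f"only {len(allowed)} non-motif positions exist"
        )
    rng = np.random.default_rng(seed)
    sites = rng.choice(len(allowed), size=k, replace=False)
    seq = list(p.seq)
    for s in sites:
        i = allowed[s]
        choices = [a for a in AA20 if a != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    return ProteinSeq(
        f"{p.id}|id{target_identity:g}", "".join(seq), is_partial=p.is_partial
    )
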