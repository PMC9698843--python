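"""Sequence and tree I/O plus basic strand/translation operations.

All genomic coordinates used across the package are 1-based and inclusive on
the forward strand; conversion to other conventions happens only at I/O
boundaries. DNA is stored uppercase over {A,C,G,T,N}; protein sequences use
the 20 standard letters plus X (unknown) and ``*`` (stop).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*", "-", "."}

VALID_FRAMES = (1, 2, 3, -1, -2, -3)

FASTA_WRAP = 60


class FastaError(ValueError):
    """Base class for FASTA parsing problems."""


class EmptyFastaError(FastaError):
    """The file contained no records."""


class DuplicateIdError(FastaError):
    """Two records share an identifier."""


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


@dataclass(frozen=True)
class GenomicContig:
    """A genomic sequence with 1-based inclusive forward-strand numbering."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"contig {self.id!r}: illegal DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Forward-strand slice, 1-based inclusive on both ends."""
        if not (1 <= start <= end <= len(self.seq)):
            raise ValueError(
                f"coordinates {start}..{end} outside contig {self.id!r} "
                f"(length {len(self.seq)})"
            )
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence.

    ``is_partial`` marks records known to be fragments.  ``is_raw_frame``
    marks raw six-frame translations, the only context where internal stop
    characters are legal.  ``meta`` carries provenance such as merge-junction
    positions.
    """

    id: str
    seq: str
    is_partial: bool = False
    is_raw_frame: bool = False
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"protein {self.id!r}: illegal residues {sorted(bad)}"
            )
        if not self.is_raw_frame and "*" in self.seq[:-1]:
            raise ValueError(
                f"protein {self.id!r}: internal stop in a non-raw-frame record"
            )

    def __len__(self) -> int:
        return len(self.seq)


SeqLike = Union[GenomicContig, ProteinSeq]


def _looks_like_dna(s: str) -> bool:
    return bool(s) and set(s.upper()) <= DNA_ALPHABET


def read_fasta(path, kind: str = "auto") -> list[SeqLike]:
    """Read a FASTA file into contigs or proteins.

    Parameters
    ----------
    path : str or Path
        FASTA file; any line-wrap width is accepted.
    kind : {"auto", "dna", "protein"}
        Record type. ``auto`` calls a record DNA when every character is in
        {A,C,G,T,N}, protein otherwise.

    Raises
    ------
    EmptyFastaError, DuplicateIdError, AlphabetError
    """
    if kind not in ("auto", "dna", "protein"):
        raise ValueError(f"unknown kind {kind!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[SeqLike] = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        s = str(rec.seq).upper()
        if kind == "dna" or (kind == "auto" and _looks_like_dna(s)):
            out.append(GenomicContig(rec.id, s))
        else:
            out.append(ProteinSeq(rec.id, s, is_raw_frame=True))
    return out


def write_fasta(records: Iterable[SeqLike], path) -> None:
    """Write records as FASTA, wrapped at 60 columns, input order preserved."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqrecs)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"illegal DNA characters {sorted(bad)}")
    return str(Seq(seq.upper()).reverse_complement())


def translate(
    seq: str,
    frame: int = 1,
    table: int = 1,
    record_id: str = "translation",
) -> ProteinSeq:
    """Translate a DNA string in one of the six frames.

    Frames 1..3 start at the first, second, third nucleotide of the forward
    strand; frames -1..-3 do the same on the reverse complement. A trailing
    partial codon is dropped. Stops render as ``*``; codons containing N
    render as X.
    """
    if frame not in VALID_FRAMES:
        raise ValueError(f"invalid frame {frame!r}; expected one of {VALID_FRAMES}")
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"illegal DNA characters {sorted(bad)}")
    if frame < 0:
        s = str(Seq(s).reverse_complement())
    s = s[abs(frame) - 1 :]
    s = s[: len(s) - (len(s) % 3)]
    aa = str(Seq(s).translate(table=table))
    return ProteinSeq(record_id, aa, is_raw_frame=True)


# ---------------------------------------------------------------------------
# Alignment and tree writers
# ---------------------------------------------------------------------------

def _check_alignment(alignment: Sequence[ProteinSeq]) -> int:
    if not alignment:
        raise ValueError("empty alignment")
    n = len(alignment[0].seq)
    for row in alignment:
        if len(row.seq) != n:
            raise ValueError(
                f"ragged alignment: {row.id!r} has length {len(row.seq)}, "
                f"expected {n}"
            )
    return n


def write_phylip(alignment: Sequence[ProteinSeq], path) -> None:
    """Relaxed PHYLIP: header line, then one 'name  sequence' line per taxon."""
    nchar = _check_alignment(alignment)
    with open(path, "w") as fh:
        fh.write(f" {len(alignment)} {nchar}\n")
        for row in alignment:
            fh.write(f"{row.id}  {row.seq}\n")


MRBAYES_TEMPLATE = """\
[ Template Bayesian-inference block; uncomment and edit to use.
begin mrbayes;
    lset rates=equal;
    prset aamodelpr=fixed(wag);
    mcmc ngen=1000000 nchains=4 temp=0.2 samplefreq=100;
    sump burninfrac=0.25;
    sumt burninfrac=0.25;
end;
]
"""


def write_nexus(
    alignment: Sequence[ProteinSeq], path, mrbayes_template: bool = True
) -> None:
    """NEXUS with a protein DATA block usable by common Bayesian tools."""
    nchar = _check_alignment(alignment)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"    dimensions ntax={len(alignment)} nchar={nchar};\n")
        fh.write("    format datatype=protein gap=- missing=?;\n")
        fh.write("    matrix\n")
        width = max(len(r.id) for r in alignment) + 2
        for row in alignment:
            fh.write(f"    {row.id:<{width}}{row.seq}\n")
        fh.write("    ;\nend;\n")
        if mrbayes_template:
            fh.write("\n" + MRBAYES_TEMPLATE)


def newick_string(tree) -> str:
    """Serialize a tree (skbio TreeNode or PhyloTree) to Newick.

    Branch lengths are printed to 6 decimals; a length-less root is allowed.
    """
    root = getattr(tree, "root", tree)
    if callable(root):  # a bare tree node: .root is a method, not our wrapper
        root = tree
    if root.is_tip():
        raise ValueError("empty or single-leaf tree cannot be serialized")

    def fmt(node) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            label = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            label += f":{node.length:.6f}"
        return label

    return fmt(root) + ";"


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def fasta_string(records: Iterable[SeqLike]) -> str:
    """FASTA text for in-memory use (same dialect as write_fasta)."""
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=FASTA_WRAP)
    writer.write_file(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    )
    return buf.getvalue()
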