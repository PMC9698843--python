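"""Degenerate-motif scanning and p25alpha domain architecture classification.

The p25alpha domain (~160 aa, Pfam PF05517) is bounded here by two
signatures: it generally starts with LxxxF(Y)xxFxxF, and its C-terminal part
carries the glycine-rich Rossmann-like motif GxGxGxxGR, near which the
microtubule-binding region maps. A fungal-type TPPP pairs one complete
p25alpha domain with a partial, Rossmann-only C-terminal duplicate; that
duplication is what the classifier detects.

Motif patterns use a small grammar: an uppercase letter is an exact residue,
``x`` (case-insensitive) a wildcard, and a parenthesized letter an
alternative to the letter before it, so ``F(Y)`` matches F or Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqio import ProteinSeq

START_MOTIF_SPEC = "LxxxF(Y)xxFxxF"
ROSSMANN_SPEC = "GxGxGxxGR"

# domain-window defaults: the complete domain spans roughly 160 residues,
# so a Rossmann motif must end within [L_MIN, L_MAX] of the start signature
L_MIN = 100
L_MAX = 200
NOMINAL_DOMAIN_LEN = 160
PARTIAL_PAD = 40


class PatternError(ValueError):
    """Malformed motif pattern specification."""


@dataclass(frozen=True)
class MotifPattern:
    id: str
    elements: tuple  # each element: frozenset of allowed residues, or None (wildcard)
    spec: str

    @property
    def length(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    matched: str


@dataclass
class DomainAnnotation:
    kind: str  # "complete_p25alpha" | "partial_p25alpha"
    start: int
    end: int
    start_motif: Optional[MotifHit] = None
    rossmann: Optional[MotifHit] = None
    rossmann_absent: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("complete_p25alpha", "partial_p25alpha"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.kind == "complete_p25alpha" and self.start_motif is None:
            raise ValueError("complete domain requires a start motif")
        if self.kind == "partial_p25alpha" and self.start_motif is not None:
            raise ValueError("partial domain must not carry a start motif")
        if self.end < self.start:
            raise ValueError("domain end before start")


@dataclass
class ArchitectureCall:
    label: str  # "fungal_type" | "single_complete" | "partial_only" | "none"
    domains: list
    notes: list = field(default_factory=list)


def compile_pattern(spec: str, pattern_id: Optional[str] = None) -> MotifPattern:
    """Compile a degenerate motif specification.

    >>> compile_pattern("GxGxGxxGR").length
    9
    """
    if not spec:
        raise PatternError("empty pattern")
    elements: list = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c in ("x", "X") and not (i + 1 < len(spec) and spec[i + 1] == "("):
            elements.append(None)
            i += 1
        elif c.isalpha() and c.isupper():
            allowed = {c}
            i += 1
            while i < len(spec) and spec[i] == "(":
                j = spec.find(")", i)
                if j == -1:
                    raise PatternError(f"dangling parenthesis in {spec!r}")
                alt = spec[i + 1 : j]
                if len(alt) != 1 or not alt.isalpha():
                    raise PatternError(
                        f"alternative must be a single letter, got {alt!r}"
                    )
                allowed.add(alt.upper())
                i = j + 1
            elements.append(frozenset(allowed))
        elif c == "(":
            raise PatternError(f"alternative with no preceding residue in {spec!r}")
        else:
            raise PatternError(f"unexpected character {c!r} in {spec!r}")
    if all(e is None for e in elements):
        raise PatternError("pattern must have at least one non-wildcard element")
    return MotifPattern(pattern_id or spec, tuple(elements), spec)


def scan_motif(p: ProteinSeq, pat: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) windows of ``p`` matching ``pat``."""
    hits = []
    n, m = len(p.seq), pat.length
    for start in range(n - m + 1):
        window = p.seq[start : start + m]
        ok = True
        for c, elem in zip(window, pat.elements):
            if elem is not None and c not in elem:
                ok = False
                break
        if ok:
            hits.append(MotifHit(pat.id, p.id, start + 1, start + m, window))
    return hits


def annotate_p25alpha(
    p: ProteinSeq,
    start_motif: MotifPattern | str = START_MOTIF_SPEC,
    rossmann: MotifPattern | str = ROSSMANN_SPEC,
    l_min: int = L_MIN,
    l_max: int = L_MAX,
    nominal_len: int = NOMINAL_DOMAIN_LEN,
    partial_pad: int = PARTIAL_PAD,
) -> list[DomainAnnotation]:
    """Annotate complete and partial p25alpha domains on a protein.

    A complete domain is a start-signature hit paired (greedily, left to
    right) with the first free Rossmann hit ending within [l_min, l_max]
    residues of the signature start; a start signature with no such Rossmann
    still yields a complete domain flagged ``rossmann_absent`` (the motif is
    genuinely missing from one domain in several chytrid and blastoclad
    proteins). Rossmann hits left unpaired become partial domains padded
    ``partial_pad`` residues upstream, clipped to the protein and to the
    previous annotation.
    """
    if isinstance(start_motif, str):
        start_motif = compile_pattern(start_motif, "p25alpha_start")
    if isinstance(rossmann, str):
        rossmann = compile_pattern(rossmann, "rossmann_like")
    start_hits = scan_motif(p, start_motif)
    ross_hits = scan_motif(p, rossmann)

    used_ross: set[int] = set()
    paired: list[DomainAnnotation] = []
    for sh in start_hits:
        if any(d.start <= sh.start <= d.end for d in paired):
            continue  # start signature inside an already-called domain
        match = None
        for k, rh in enumerate(ross_hits):
            if k in used_ross or rh.start <= sh.start:
                continue
            span = rh.end - sh.start + 1
            if l_min <= span <= l_max:
                match = k
                break
        if match is not None:
            rh = ross_hits[match]
            used_ross.add(match)
            paired.append(
                DomainAnnotation(
                    "complete_p25alpha", sh.start, rh.end,
                    start_motif=sh, rossmann=rh,
                )
            )
        else:
            end = min(sh.start + nominal_len - 1, len(p.seq))
            paired.append(
                DomainAnnotation(
                    "complete_p25alpha", sh.start, end,
                    start_motif=sh, rossmann_absent=True,
                )
            )
    for k, rh in enumerate(ross_hits):
        if k in used_ross:
            continue
        if any(d.start <= rh.start and rh.end <= d.end for d in paired):
            continue  # Rossmann inside a rossmann_absent complete domain
        start = max(1, rh.start - partial_pad)
        paired.append(
            DomainAnnotation("partial_p25alpha", start, rh.end, rossmann=rh)
        )
    paired.sort(key=lambda d: (d.start, d.end))
    # clip overlaps so the annotation list is an ordered, disjoint chain
    for prev, cur in zip(paired, paired[1:]):
        if cur.start <= prev.end:
            cur.start = prev.end + 1
    return paired


def classify_architecture(domains: Sequence[DomainAnnotation]) -> ArchitectureCall:
    """Label a domain list with its TPPP architecture.

    fungal_type: a complete p25alpha domain followed by a partial one
    C-terminal to it; single_complete: exactly one complete, no partial;
    partial_only: only partial domains; none: anything else (including no
    domains at all).
    """
    doms = list(domains)
    for prev, cur in zip(doms, doms[1:]):
        if cur.start < prev.start:
            raise ValueError("domains must be ordered by start position")
    kinds = [d.kind for d in doms]
    n_complete = kinds.count("complete_p25alpha")
    n_partial = kinds.count("partial_p25alpha")
    fungal = any(
        a.kind == "complete_p25alpha" and b.kind == "partial_p25alpha"
        for i, a in enumerate(doms)
        for b in doms[i + 1 :]
    )
    if fungal:
        label = "fungal_type"
    elif n_complete == 1 and n_partial == 0:
        label = "single_complete"
    elif n_partial > 0 and n_complete == 0:
        label = "partial_only"
    else:
        label = "none"
    return ArchitectureCall(label, doms)
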