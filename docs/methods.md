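# Methods

This note documents the models and numerical choices behind `p25scan`: how
gene models are reconstructed from protein homology, how p25alpha domains
are called, what the synthetic-data generator does and does not emulate,
and where the method's identifiability limits lie.

## Coordinates and sequence conventions

All genomic coordinates are 1-based and inclusive on the forward strand;
reverse-strand features carry forward coordinates plus a strand flag, and
the assembly machinery works internally in reverse-complement ("gene
forward") space for minus-strand genes. DNA is uppercase over {A,C,G,T,N};
codons containing N translate to X. `*` (stop) is legal only in raw frame
translations, never inside an assembled coding sequence. FASTA output wraps
at 60 columns; any wrap is accepted on input.

## Pairwise alignment

Local and global alignment are exact affine-gap dynamic programs over
BLOSUM62 with BLAST-like defaults: gap open 11, gap extend 1, a gap of
length *k* costing 11 + *k*. Traceback is deterministic — the start cell is
the first maximum in row-major order and ties resolve diagonal → up → left
— so every downstream result is reproducible bit for bit. Percent identity
is identities over all alignment columns including gaps, rounded half-up to
two decimals; query cover is the aligned query span over the query length,
rounded half-up to a whole percent. These are the conventions of BLAST
tabular output, which the alignment statistics are meant to be read
against. E-values and bit scores are deliberately out of scope: score
thresholds here are raw-score parameters.

The kernels are numba-compiled; a reference protein against a multi-
kilobase contig in all six frames takes milliseconds, which is what makes
the seeded recovery experiments (hundreds of full reconstructions) cheap.

## Homology anchoring

`anchor_protein_to_genome` translates the contig in all six frames, finds
every local alignment of the reference scoring at least
`min_segment_score` (default 50; found blocks are masked and the flanks
re-searched, so several exons in one frame are all reported), splits
alignments at runs of ≥ `max_gap_cols` (default 10) gap columns — the
footprint of an intron bridged within one frame — and back-maps each block
to nucleotides: peptide position *p* in frame *f* ≥ 1 occupies nucleotides
*f* + 3(*p*−1) … *f* + 3(*p*−1)+2.

Raw Smith–Waterman blocks systematically overshoot exon boundaries: an SW
optimum never ends on a net-negative run, and translated intron or
off-frame sequence yields occasional high-scoring coincidental matches
(a single W/W column scores +11). Three reconciliation steps correct this:

1. **Block-end trimming.** Each block is cut to its maximum-scoring
   contiguous column run after subtracting a per-column baseline (default
   1.0). Genuine homologous blocks average several points per column and
   survive; sparsely matching junk (expected identity ~5%) goes negative
   and is trimmed. Aligning anything onto a translated stop codon is
   additionally given a prohibitive score (−100), since a stop can never
   lie inside a true coding exon.
2. **Chain selection** (pipeline): the highest-scoring subset of blocks
   that is disjoint and ascending on the genome and non-decreasing on the
   reference — one gene's exon chain — discarding frame-shadow and
   secondary hits.
3. **Query-overlap resolution** (pipeline): every reference residue is
   encoded by exactly one exon, so when adjacent chain segments claim
   overlapping reference intervals (the signature of residual junk drift),
   the overlapping columns are removed from whichever side scores them
   worse.

After these steps anchor boundaries are correct to within a few codons;
the splice-refinement stage does the rest.

## Intron inference and splice refinement

Between consecutive anchored segments, the gap length *g* and its frame
offset *g* mod 3 are computed; a non-zero offset means the blocks cannot
share one reading frame, recorded as `frame_shift` evidence. By default
the intron is the whole inter-segment gap — the conservative reading when
no splice-site model is invoked.

With `refine_splice`, boundary pairs (s, e) sliding the default boundaries
by up to `slide_max` nucleotides are enumerated, subject to: canonical GT
at the donor, AG at the acceptor, intron length ≥ 4, and (s+e) ≡ 0 mod 3
(re-assigning bases between exon and intron must not change the coding
length mod 3). Slides may be negative — exon bases re-assigned to the
intron — which is how over-extended anchors are repaired. When several
candidates exist and the reference is available, each candidate junction
is re-translated (eight codons of context either side plus the bridged
split codon) and locally aligned to the reference residues the two anchors
place at the junction; the best-scoring candidate wins, with ties resolved
toward non-negative, minimal slides. `infer_intron`'s own default radius
is 6 nt; the pipeline searches 15 nt, sized to cover up to four codons of
anchor drift plus split-codon bases.

Intron phase is the cumulative coding length upstream of the intron mod 3
(phase 1 = the intron falls after the first base of a codon, matching the
convention in which a glycine split 1+2 across an exon junction marks a
phase-1 intron). The assembler recomputes all phases from the final exon
chain, so phase bookkeeping is consistent with whatever start codon was
chosen.

**Identifiability limit.** Two GT…AG placements can encode an identical
protein: if the donor and acceptor both shift by a net multiple of 3 and
the swapped bases form synonymous split codons (an observed case: CCG vs
CCC → Pro and AGC vs TCC → Ser), no protein-level evidence can
distinguish them. On such junctions the reconstruction returns one of the
equivalent placements; the protein, intron phases and exon count are still
exact. The test suite asserts boundary exactness up to this documented
ambiguity.

## Gene assembly

Exon boundaries between segments come from the intron calls. The first
exon keeps its own start when it already begins with ATG (the anchored
homology reaches the methionine); otherwise in-frame upstream ATGs with no
intervening in-frame stop are viable starts — all are reported, the most
upstream is used for the CDS, and more than one sets the
N-terminus-ambiguous flag rather than silently choosing. No viable start
sets `n_terminus_missing`; if a homolog then shows an exon boundary where
the model protein begins (`assess_upstream_exon`), an additional upstream
exon is hypothesized and the hypothesized exon count exceeds the supported
count by one. The last exon extends to the first in-frame stop within
`stop_scan_limit` (default 3000 nt, bounding runaway extension); no stop
sets `c_terminus_missing`. An internal stop inside an anchored segment is
a hard error naming the genomic coordinate.

Partial proteins merge by the longest exact suffix/prefix overlap of at
least `min_overlap` residues (default 3); an overlap ≥ 80% identical but
imperfect raises a conflict error, and disjoint fragments concatenate with
the junction position recorded in metadata rather than guessed away.

Homolog intron comparison maps each model intron to a residue position
(the residue whose codon it interrupts), then to an alignment column; a
homolog boundary of equal phase within `tol` aligned columns (default 2)
adds `homolog_boundary` evidence.

## Domain annotation and classification

The p25alpha domain is recognized by two degenerate signatures, compiled
from a small grammar (uppercase = exact residue, `x` = wildcard,
parenthesized letter = alternative to the preceding letter): the start
signature `LxxxF(Y)xxFxxF` and the C-terminal Rossmann-like `GxGxGxxGR`.
Scanning is exhaustive over all windows, overlapping hits included.

A complete domain pairs a start-signature hit with the first free Rossmann
hit ending within [`l_min`, `l_max`] residues of the signature start
(defaults 100–200, bracketing the ~160-residue domain). A start signature
with no Rossmann in window still yields a complete domain flagged
`rossmann_absent` — the motif is genuinely missing from one domain in
several chytrid and blastoclad proteins — with a nominal 160-residue span.
Unpaired Rossmann hits become partial domains padded `partial_pad`
(default 40) residues upstream, clipped to the protein and the previous
annotation. Classification is then a pure function of domain kinds and
order: a complete domain with a partial one C-terminal to it is
`fungal_type`; exactly one complete and nothing else is `single_complete`;
only partials is `partial_only`; anything else is `none`. Profile-HMM
scoring is intentionally not used: the two signatures plus homology are
the identification criteria this workflow encodes, and apicortin-like
architectures (partial p25alpha + DCX) are out of scope by design.

## Distance tree

p-distance uses pairwise deletion by default because the interdomain
region of fungal-type TPPPs aligns poorly — complete deletion would
discard most informative columns along with it. Neighbor joining is the
canonical Q-matrix algorithm with deterministic ties (earliest pair in
current node order) and negative branch-length estimates clamped to zero
with a flag on the tree; on additive matrices it reproduces the generating
topology and path lengths to 1e-9. This is a sanity tree: Bayesian
inference is the job of external tools, for which the NEXUS writer emits a
commented template block.

## Synthetic data: what it emulates, what it does not

The generator mirrors the study system's structure: a fungal-type protein
(start signature and Rossmann ~160 residues apart, an interdomain linker,
a partial C-terminal duplicate), back-translated with uniform codon choice
into a multi-exon gene with GT…AG introns at requested lengths and phases,
flanked by 300 nt of random sequence, with optional ATG and stop; and
homologs derived by seeded point substitutions at a target identity
(±2 points), optionally sparing motif positions. Test-grid conditions:
exon counts 1–6 over mixed phases, intron lengths 60–110 nt, and reference
divergence up to 20%, matching the 35–43% identity neighborhood only in
the motif-preserved sense — full-distance homologs (~40% identity) are
used for alignment-statistics checks, not for boundary recovery claims.

Not emulated: codon usage bias, indels (an option exists but defaults to
0 so truth coordinates stay exact), splice-site consensus beyond GT…AG,
intergenic gene content, and sequencing error. Passing tests therefore
demonstrate correctness of the reconstruction calculus under clean
assumptions, not robustness to assembly artifacts or non-canonical splice
sites.

## Numerical and degenerate-input choices

Rounding of identity/cover is decimal half-up to match printed-report
conventions. Empty local alignments (all-negative score) return score 0
with empty intervals. `align_global` accepts one empty sequence (an
all-gap column alignment); `align_local` rejects empty input. NJ requires
≥ 3 taxa; p-distance raises on a pair with zero comparable columns. The
mutation generator raises when the substitution budget exceeds available
non-motif positions. All randomness flows through explicit
`numpy.random.default_rng` seeds; there is no global random state, and
identical inputs, parameters and seeds produce byte-identical JSON
summaries.

## Problem sizes in the shipped experiments

The seeded experiments run at sizes chosen to keep the whole suite fast on
a single CPU while exercising every code path: a 72-cell noiseless grid
(12 seeds × 6 exon-count/phase combinations), 200 divergence replicates of
a 4-exon gene, 1000 random proteins for the motif oracle, 100 random
8-leaf additive matrices for NJ, and length-≤8 peptides for the exhaustive
alignment-path oracle. These are statements of the package's test design,
and the acceptance script reports the size used alongside every value.
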