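# p25scan

Homology-anchored gene-model reconstruction and p25alpha/TPPP domain
architecture classification.

## The problem

TPPP-like proteins (tubulin polymerization promoting proteins) are defined
by the ~160-residue p25alpha domain (Pfam PF05517), whose phyletic
distribution tracks the eukaryotic flagellum. In early-branching,
flagellated fungi a distinctive **fungal-type TPPP** occurs: one complete
p25alpha domain followed by a partial, C-terminal duplicate that carries
only the domain's Rossmann-like `GxGxGxxGR` signature. Finding such a
protein in a newly sequenced genome often means working from an unannotated
whole-genome-shotgun contig and a handful of partial protein records:
anchoring known homologs onto six-frame translations, arguing introns into
existence from reading-frame arithmetic, enumerating start codons, and
completing the C-terminus at the first in-frame stop.

`p25scan` packages that manual curation workflow for people doing
comparative genomics of TPPP-family proteins:

* **seqio** — FASTA I/O, strand operations, six-frame translation, and
  writers for relaxed PHYLIP, NEXUS (with an inert Bayesian-tool template
  block) and Newick. Coordinates are 1-based and inclusive everywhere.
* **pairwise** — exact Smith–Waterman / Needleman–Wunsch with affine gaps
  (BLOSUM62, gap open 11, extend 1; a gap of length *k* costs 11 + *k*),
  BLAST-style percent identity / query cover, and
  `anchor_protein_to_genome`, which reports homologous coding blocks on a
  contig with frame-correct nucleotide back-mapping.
* **genemodel** — the reconstruction calculus: a gap of length *g* between
  anchored blocks with *g* mod 3 ≠ 0 cannot be read through in one frame
  (frame-shift evidence for an intron); intron phase follows from the
  cumulative coding length; optional GT…AG splice refinement re-translates
  each candidate junction against the reference; start-codon enumeration,
  stop-codon completion, partial-protein merging and homolog exon-boundary
  comparison complete the model.
* **domains** — degenerate-motif scanning (`LxxxF(Y)xxFxxF` start
  signature, `GxGxGxxGR` Rossmann-like signature) and architecture
  classification: `fungal_type`, `single_complete`, `partial_only`, `none`.
* **phylo_lite** — p-distances (pairwise deletion) and canonical neighbor
  joining as an in-repo sanity tree; Bayesian inference belongs to external
  tools fed by the NEXUS writer.
* **synthetic** — ground-truth generator: fungal-type proteins with planted
  motifs, multi-exon genes with introns of chosen length and phase, and
  point-mutated homologs at a target percent identity.

## Worked example

Simulate a four-exon fungal-type gene (phase-1 introns), reconstruct it
from its own protein, and classify the result:

```bash
p25scan simulate --seed 5 --out-prefix sim
p25scan run --contig sim.contig.fna --ref sim.protein.faa \
            --out-dir out --refine-splice
```

`out/summary.json` then contains (abridged):

```
exons:   [[301, 487], [558, 746], [824, 1009], [1094, 1281]]
introns: [(488, 557,  70 nt, phase 1, {frame_shift, splice_motif}),
          (747, 823,  77 nt, phase 1, {frame_shift, splice_motif}),
          (1010, 1093, 84 nt, phase 1, {splice_motif})]
domains: [(complete_p25alpha, 12, 171), (partial_p25alpha, 192, 240)]
architecture: fungal_type
```

Reading the numbers: the first two introns announce themselves by frame
arithmetic — 70 and 77 are not divisible by 3, so the flanking anchored
blocks cannot share a reading frame — while the third (84 nt) is
frame-neutral and rests on its GT…AG boundaries and the reference-scored
junction. All three are phase 1 (the intron interrupts a codon after its
first base). The protein carries one complete p25alpha domain (residues
12–171, both signatures) and a partial duplicate around the second
Rossmann-like motif: a fungal-type TPPP. The exon coordinates match the
generator's planted truth exactly.

The same stages are available separately (`p25scan anchor`, `genemodel`,
`classify`, `tree`) and as library functions (`reconstruct_gene`,
`annotate_p25alpha`, `neighbor_joining`, …).

## Limitations

Anchoring is exact dynamic programming over all six frames — fine for
contigs up to a few hundred kilobases, not a substitute for heuristic
seeding on whole genomes. Splice refinement assumes GT…AG introns. The
classifier deliberately uses the two degenerate signatures rather than a
profile HMM, so proteins with heavily diverged signatures (or apicortins,
whose partial p25alpha pairs with a DCX domain) fall into `partial_only` or
`none`. See `docs/methods.md` for the model, parameter defaults and known
identifiability limits.
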