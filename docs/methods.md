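# Methods

This note documents the models and procedures behind `mitomine`, the
assumptions they make, the defaults and why they were chosen, and what
the synthetic benchmark does and does not demonstrate about real data.

## The problem setting

A metazoan mitogenome is a circular molecule of ~15 kb with a nearly
universal inventory: 13 protein-coding genes, tRNAs, the 12S and 16S
rRNAs, and one noncoding control region (D-loop). Because mitochondrial
transcription is polycistronic and mature transcripts cover the coding
portion of the molecule, cDNA (RNA-seq) contigs can be mined for
mitochondrial regions and tiled into a consensus genome against an
annotated congener reference. Two structural facts drive the design:

1. the control region is absent from mature transcripts, so a
   transcriptome-based assembly always reports it as a gap;
2. gene content and order are conserved within a genus, so the congener
   reference frame is a valid coordinate system for the consensus.

## Synthetic data generator

`GenomeLayout` describes a gap-free, overlap-free circular genome; the
default layout has 37 regions in conserved *Macrobrachium*-like order
(13 PCGs, 21 tRNAs, 2 rRNAs, one 793-bp control region; all light-strand
except tRNA-Gln), totalling 15,527 bp, linearized at the COI start.
Sequence is drawn i.i.d. with a target A+T fraction of 0.61 (the
observed palaemonid value; configurable). Every PCG starts with ATG,
ends with TAA/TAG, and contains no internal in-frame stop under the
invertebrate mitochondrial genetic code (NCBI table 5, where TGA = Trp
and the only stops are TAA/TAG).

**Evolution** is a per-site Kimura-1980 substitution process with
expected divergence `d_sim` (substitutions/site) and
transition/transversion rate ratio `kappa` (default 2): with
`beta*t = d/(kappa+2)`, change probabilities follow the K2P matrix
exponential, so `count_substitutions` + `k2p_distance` on a
(reference, evolved) pair is an estimator of `d_sim` — the parameter-
recovery surface of the test suite. There are no indels, so
coordinates project 1:1 from reference to target; this is what makes a
reference-frame consensus exact. By default, substitutions that would
create an internal in-frame stop in a PCG are reverted
(`preserve_orfs`), a minimal stand-in for purifying selection; without
it a diverged target is not annotatable, unlike any real congener. The
reversion touches ~0.1% of sites at genus-level divergence and is
excluded from the parameter-recovery benchmarks (which use PCG-free
layouts).

**Libraries.** Six libraries (androgen gland, hepatopancreas, muscle ×
two replicates — the study design the pipeline targets) each contribute
`n_contigs` contigs (default 80; the source study reports no per-library
coverage, so this is a free parameter chosen to give comfortable
coverage at ~15 kb). The default `transcript` sampling mode draws each
contig as a run of adjacent complete features inside the allowed region
— the polycistronic-transcript picture — grown toward a uniform target
length in [200, 1200] bp. This matters: with uniform-position sampling,
positions flush against an excluded interval are covered with
probability ~`n/L` per contig, so the observed gap would always bleed
into neighbouring genes; feature-run sampling reproduces the sharp
gap boundary that real transcript data shows at the control region. A
literal `uniform` mode (uniform lengths at uniform circular positions)
is available. Contigs are emitted as-is or reverse-complemented with
probability 0.5, with i.i.d. substitution errors at `error_rate`
(default 0).

## Mining

The search is seed-and-verify. An exact k-mer index (k = 11) over the
reference regions produces seed matches that are projected onto genome
diagonals (`genome position − contig position`) and clustered with a
±30 nt tolerance. Each cluster with ≥ 4 seeds (`min_seeds`) defines a
reference window — the contig's diagonal projection padded by 30 nt —
which is aligned to the contig by exact local Smith-Waterman with
affine gaps (match +1, mismatch −1, gap open 2, extend 1; a gap of
length L costs 2 + L), using Biopython's C `PairwiseAligner`. The
alignment is then split at region boundaries into per-region hits, each
with its own coordinates, identity and score.

Design notes:

- *Why cluster across regions instead of searching each region
  separately?* At genus-level divergence (~17% observed) a 60-bp tRNA
  has a ~30% chance of containing no intact 11-mer, so per-region
  seeding systematically loses small regions, and independent local
  alignments leave 1-bp holes at contig boundaries (terminal mismatch
  trimming). A contig spanning several genes anchors one contiguous
  alignment — the same effect as laying whole contigs against the full
  genome in a ClustalW editor — and the split recovers per-region
  records.
- *Why `min_seeds` = 4?* A random exact match of length ≥ k+3 between
  unrelated sequence is rare (~4^−14 per position pair), whereas two
  overlapping seeds arise from any 12-bp match and, measured on the
  default benchmark, triggered hundreds of useless whole-contig
  alignments per run.
- *Exactness.* Within a window the score is the true optimal
  local-alignment score (no X-drop or banding heuristics); the window
  covers the optimum whenever indels do not exceed the 30-nt pad, which
  is exact for the substitution-only generator and comfortable for real
  small indels. The test suite checks score equality against an
  independent full-matrix Gotoh implementation.

Hits are filtered inclusively: identity ≥ 0.75 and aligned length ≥
min(50 nt, region length) — the cap keeps 30-bp tRNAs findable, which a
flat 50-nt threshold would make structurally unrecoverable. Defaults
target ≤ ~22% nucleotide divergence (the within-genus range); they are
not claimed to replicate any specific unpublished BLAST wrapper.

## Consensus

Hits from all libraries are projected onto the reference frame. Each
aligned contig base contributes a call weighted by its hit's identity
(down-weighting misassigned or paralogous fragments); contig insertions
relative to the reference are dropped, deletions contribute nothing.
Per position, the base with the highest summed weight wins; ties fall
back to the plurality of distinct libraries, then to the
lexicographically smallest base — fully deterministic. Uncovered
positions become `N` and are merged into maximal unrecovered intervals,
across the origin if the genome is circular; the gap report lists each
interval with the reference features it overlaps and a totals row.

The consensus lives on the reference coordinate frame; there is no
de-novo scaffolding. How the original study resolved inter-library
disagreements is not recorded anywhere; the weighted-majority rule is
this package's own documented choice.

## Annotation

Reference features are copied onto the consensus (same frame by
construction). Features wholly inside `N` runs are flagged unrecovered;
partially covered ones are trimmed to their recovered extent and flagged
incomplete. Each recovered PCG is then refined: the start codon is the
accepted triplet closest to the projected start within ±18 nt in frame
(ATG preferred on distance ties; accepted set
{ATG, GTG, ATT, ATC, ATA, ACG, ACT, CTT, TAT} — canonical starts plus
every alternative initiation codon reported in malacostracan
mitogenomes); the stop is the first in-frame terminator ending at or
after the projected end, searched over {TAA, TAG, TGA} with a logged
warning when TGA is chosen (it encodes Trp under the invertebrate code,
yet appears as the terminator of Cytb in published crustacean tables);
the frame in between must be free of genuine stops (TAA/TAG). If no
accepted start exists in the window the projected coordinates are kept
with a warning; a gene whose every candidate frame contains an internal
stop is reported and left at projected coordinates by the pipeline
orchestrator (the low-level `refine_pcg` raises).

Bookkeeping: size = end − start + 1; amino acids = size/3 − 1 (the
terminal codon encodes no residue; truncated T/TA stops are not
supported and raise); `In` = start(next) − end − 1 on the recovered,
start-sorted features, the last feature wrapping to the first on a
circular genome. For a gap-free tiling annotation, sizes and signed
`In` values sum to the genome length — asserted as a test invariant.

## Composition

Percentages are computed over counted A/C/G/T only; `N` and ambiguity
characters are excluded from numerator and denominator, and the
reported size is the counted-base total. Class scopes (PCGs, tRNAs,
rRNA) use the positional union of the class's recovered intervals, so
overlapping genes are counted once — the only order-independent reading
of "overlaps removed"; noncoding spacers are visible only in the
whole-genome row. All features are counted on the forward strand (class
tables report one number per class, not per strand). Values stay at
full precision internally and are rounded half-up to two decimals only
when serialized.

## Divergence and trees

`count_substitutions` classifies mismatches over gap-free compared
columns (pairwise deletion; a complete-deletion mode masking columns
gapped in *any* taxon is provided for equal-length inputs — which mode
published matrices used is generally unstated). The K2P distance is the
closed form `d = −½ ln((1−2P−Q)√(1−2Q))`; inputs outside its domain
produce NaN with a warning and propagate as explicitly undefined matrix
entries, never silently dropped.

The near-whole-genome mode ("~85% of the mitogenome") truncates every
genome at the first base of its control region — the fixed convention
here, since the region downstream of the gap cannot be compared for a
transcriptome-derived genome. Per-gene mode extracts one named gene per
taxon (strand-aware) and marks missing genes as undefined pairs.
Equal-length inputs are compared position-by-position (exact under the
substitution-only generator); unequal pairs are globally aligned first
(affine gaps, deterministic traceback from the aligner's canonical
order).

Trees are canonical neighbor joining on the Q criterion, with ties
broken by the lexicographically smallest pair of cluster labels and
negative branch lengths clamped to zero with a warning. NJ is exact on
additive matrices — verified against quartet enumeration and against
random additive six-taxon trees. Bootstrap supports come from `B`
column resamples of a star alignment (all taxa stacked on the first
taxon's coordinates; a full progressive MSA is out of scope): each
replicate yields a K2P matrix and NJ tree, and an internal edge's
support is the percentage of replicate trees containing its
bipartition. Saturated replicates (undefined distances) are skipped and
excluded from the denominator. Everything is deterministic under a
fixed seed. NJ over K2P distances stands in for likelihood-based tree
building; at within-genus distances (≤ ~0.22) it reproduces the
published groupings (the two *M. rosenbergii* accessions as siblings,
*M. nipponense* + *M. bullatum* as a cherry), which the test suite
checks on the published matrix rather than assumes.

## Problem sizes and benchmarks

The bundled benchmarks run on: the full 15,527-bp default layout with
6 × 40 contigs for round-trip and gap-reporting checks (zero divergence,
and d = 0.1 for the congener-mining check); 10-kb PCG-free genomes ×
100 seeded replicates at d ∈ {0.05, 0.2} for K2P parameter recovery
(±0.02 tolerance, ≥95% of replicates); 50 seeded pairs up to 2 kb
(5% substitutions, small indels) for alignment-score equality against
the independent DP oracle; and 4-kb quartets for bootstrap behavior.
These sizes keep the whole suite around a minute.

## Known limitations

- Substitution-only simulation: no indels, rearrangements, duplicated
  control regions, Numts or heteroplasmy; real contigs also carry
  assembly chimeras the generator does not model. Passing the
  round-trip tests therefore demonstrates correctness of the pipeline's
  bookkeeping, not robustness to structural variation.
- At genus-level divergence (d ≈ 0.2 uniform), a ~60-bp region
  occasionally drifts below the 0.75 identity threshold in a given
  realization and is honestly dropped; real tRNAs are more conserved
  than a uniform-rate model implies, so this overstates the failure
  mode. Occasional 1-bp consensus artifacts can likewise appear near
  dense mutation clusters where the optimal alignment places an indel
  pair.
- The consensus cannot assemble anything absent from the reference
  frame (novel insertions, rearranged gene orders).
- Bootstrap columns come from a star alignment anchored on the first
  taxon; for indel-free inputs this is exact, for real unequal-length
  genomes it is an approximation below a full MSA.
- Truncated stop codons (T/TA completed by polyadenylation) are treated
  as errors rather than annotated.
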