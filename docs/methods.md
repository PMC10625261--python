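# Methods

This note describes the models and procedures behind `tetrack`, the
assumptions they make, the tunable parameters, and the choices taken
where the design was genuinely open. No empirical claim here goes
beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## 1. The discovery model

The pipeline operationalizes a simple biological argument: a transposon
family that is *transcriptionally active* leaves full-length transcripts
in a cDNA collection, and a family that is *recently mobile* leaves
insertion-site polymorphisms between accession genomes. Both signals
are detectable with nothing but local alignment plus the structural
grammar of transposon termini:

* an insertion duplicates its target site, so an intact element is
  flanked by an identical short direct repeat (the TSD);
* each superfamily carries a terminal hallmark — LTR retrotransposons
  have long identical direct repeats starting `TG` and ending `CA`;
  DNA transposons (CACTA, mariner, mutator) have terminal inverted
  repeats; LINEs end in a 3′ poly(A) tract;
* at a locus where one genome has the element and another does not, the
  empty allele is flank + a *single* target-site copy + flank.

An element is called **intact** only when an exact TSD and a terminal
hallmark coincide — a deliberately strict conjunction. Either signal
alone is too easy to find by chance; requiring both keeps boundary
calls exact and superfamily labels grounded.

## 2. Alignment engine

All searches use one in-package seed-and-extend aligner.

**Seeding.** DNA-vs-DNA: exact 11-mers (`word_size`), both query
strands, against a numpy sorted-array k-mer index of the subject.
Protein-vs-translated-DNA: 3-mer BLOSUM62 neighborhood words with
threshold T = 12 (the smallest self-score of any standard-residue
3-mer is 12, so exact words always seed), filtered by the classic
two-hit rule (a second seed on the same diagonal within 64 aa) and a
≥ 4-seed cluster gate. Without these gates, neighborhood seeding
produces a seed at nearly every subject position and extension cost
explodes; with them, only genuinely homologous diagonals are extended.

**Extension.** Seed clusters define a diagonal band
(± `band_pad` = 64); a banded affine-gap local DP (Gotoh) is run with
rows vectorized in numpy. Horizontal affine gaps inside a row are
resolved with a prefix-max identity,
`E[b] = open + max_{k<b}(P[k] + (b−k)·extend)`, which removes the
sequential dependency. A gap of length k costs `gap_open +
k·gap_extend` (defaults −5, −2; DNA match/mismatch +2/−3; protein
BLOSUM62 with −11, −1). When the full matrix is at most 250k cells and
at least one seed exists, the band is widened to the whole matrix, so
the reported optimum *is* the Smith–Waterman optimum — the test suite
asserts equality against an independent full-matrix oracle on pairs up
to 300 bp, and `score ≤ oracle` always.

**Statistics.** Karlin–Altschul, `E = K·m·n·exp(−λS)`, with
(λ, K) = (0.625, 0.41) for the +2/−3 nucleotide scoring and
(0.267, 0.041) for BLOSUM62 11/1 — standard published estimates for
these scoring systems. `n` is the total subject length (total
translated length in aa for protein searches), so E scales linearly in
database size. The published operating point of the screen is
`E < 1e-10` over a matched region strictly greater than 50 bp
(translated hits count 3 nt per aligned aa column).

**Determinism.** Ties are broken by (E-value, −bit, subject id,
position); near-duplicate hits (≥ 80% reciprocal overlap in both
coordinates) are suppressed best-first.

## 3. Structural boundary definition

For each family the loci are the anchored transcript hits ± 10 kb
(`locus_flank`). Boundary proposals come from two sources:

* the **anchor extent** — exact whenever the transcript covers the
  whole element, because extension is bounded by the query;
* the **multi-copy union** — pairwise alignment of the locus window
  against up to two sibling copy windows; copies share the element and
  differ in flanks, so homology drops at the true boundary. Hits whose
  query and subject projections land on overlapping genome intervals
  are discarded (windows of nearby copies physically overlap, and a
  region trivially aligns to itself). The union may overrun a boundary
  by a base or two when flank bases coincide by chance, so it only
  *widens* a proposal when it extends clearly (> jitter) beyond the
  anchor, and the anchor extent is always tried first.

Around a proposal, `find_tsd` enumerates every TSD length in
[`tsd_len_min`, `tsd_len_max`] = [2, 20] with both boundaries jittered
within ± 5 bp (`boundary_jitter`) and reports exact direct repeats.
For element placement the candidates are ranked **jitter-first**, then
longest: ranking by length across jitter classes would let
microhomology between element termini and flank fabricate longer
pseudo-TSDs at shifted boundaries (an element ending `CA` whose left
flank happens to end `CA`; a poly(A) tail abutting an `A`). The first
candidate whose body carries a terminal feature wins:

* **TIR**: longest prefix aligning to the reverse-complemented suffix
  with ≤ 2 mismatches (`tir_max_mismatch`), minimum 10 bp
  (`tir_min_len`); checked first because it is cheap and decisive.
* **LTR pair**: best plus-strand local alignment of the body's first
  half against its second half, ≥ 80 bp (`ltr_min_len`) at ≥ 85%
  identity (`ltr_min_identity`), each repeat anchored at its body end
  within the jitter; `TG…CA` pairs preferred.
* **poly(A)**: A-fraction ≥ 0.75 (`polya_min_frac`) over the terminal
  15 bp window (`polya_window`); the tail length is the longest suffix
  whose running A-fraction stays at the threshold.

Superfamily follows from the feature + TSD: LTR pair → LTR
retrotransposon; TIR + `TA` TSD → Tc1/mariner; TIR + `CACTA` motif +
3 bp TSD → CACTA; TIR + 8–10 bp TSD → Mutator; poly(A) (no TIR/LTR) →
LINE; anything else UNCLASSIFIED. These length conventions are standard
TE taxonomy, exposed in `PipelineParams`.

## 4. Masking and curation

Each intact element is searched against the genome; hits with
`E < 1e-10` and identity ≥ 60% (`mask_min_identity`) are kept with no
low-complexity pre-filter, and same-family hits overlapping or within
20 bp (`mask_merge_gap`) are merged (extension fragments of one copy).
A merged copy is **well_defined** only if (a) its alignment covers both
reference termini within 10 bp, (b) the family's terminal feature is
detectable on the copy itself, and (c) an exact TSD flanks the
TSD-consistent placement — which also refines the copy's coordinates.
Everything else is **fragmental**. Because masking aligns the bounded
reference, curation proposals cannot overrun, and at zero divergence the
well-defined set provably coincides with the planted intact set (the
acceptance suite asserts exact equality on a 2-Mb genome).

## 5. Presence/absence classification

For each probed copy, 350 bp flanks (`probe_flank`) are cut immediately
outside the body — the TSD copies fall inside the flanks. Each flank is
searched separately against the target genome (the category definitions
are per-flank; the merged 700 bp probe is available as
`FlankProbe.probe`). A flank is UNIQUE when its best hit beats the
runner-up by ≥ 2 identity points (`unique_margin`), MULTI when ≥ 2 hits
tie within the margin, NONE without a significant hit. The joint
outcome maps to six exhaustive categories; with both flanks UNIQUE,
collinear and same-strand, the inter-flank gap decides: a gap within
[−25, 50] bp (`empty_site_gap_max`, lower bound absorbing the retained
TSD copy) is the empty site (B); a gap within ± 20% of the element
length (`shared_len_tol`) whose interval aligns to the family at ≥ 50%
coverage is shared (A); any other unique-pair geometry is recorded as D
with its reason. A NONE+MULTI combination counts as E (a missing flank
dominates). Self-comparison yields A for every copy, and on simulations
with unique flanks the B set equals the planted absence set exactly;
duplicated-background stress pushes affected loci into C/D, never into
a false B — all asserted in the acceptance suite.

## 6. TE recruitment into genes

Gene models (exons + CDS in genomic coordinates) are projected to
transcript space, partitioning each transcript into 5′ UTR | CDS |
3′ UTR (minus-strand models are flipped; UTRs may be empty). The
element library is scanned against the transcripts, the best
significant region per (transcript, family) is kept, and each region
is assigned to whichever annotation region contains ≥ 80% of it,
otherwise MIXED. Gene-level summaries report the CDS share both over
all classified genes and excluding MIXED, since a whole-gene class
assignment rule is not uniquely determined.

## 7. The synthetic-data generator

`simulate_genome` plants each family's copies into i.i.d. uniform
random background chromosomes. Design choices, and what they imply:

* **Background** is uniform random, which minimizes spurious homology
  and makes truth-based acceptance sharp. A mappability stress mode
  copies the left-flank segment (including the target site) of selected
  insertions elsewhere into the background to exercise the
  multi-mapping categories. Passing tests therefore demonstrate
  correctness of the *logic*, not robustness to real repeat landscapes
  — real genomes are ~80% repetitive and would push many loci into
  C/D, as the original screen also observed.
* **Families**: one per archetype, scaled-down but structurally
  realistic — a 5 kb LTR element (200 bp LTRs, 5 bp TSD), a 3 kb LINE
  (15 A tail, 12 bp TSD), a 4 kb CACTA (20 bp TIRs starting `CACTA`,
  3 bp TSD), a 1.3 kb mariner (26 bp TIRs, fixed `TA` site), a 3.5 kb
  mutator-like element (60 bp TIRs, 9 bp TSD). Each carries a ~1 kb
  internal ORF whose translation serves as the family's transposase
  probe for the translated screen.
* **Insertion** duplicates the target site exactly: genome length =
  background + Σ(body + one TSD) — an exact conservation law the tests
  check. Mariner sites are written as `TA` into the background so the
  fixed target-site rule holds in every accession.
* **Divergence** is independent per-base substitution on copy bodies
  only (no indels, TSDs untouched), keeping TSD arithmetic exact. The
  default family divergence is 2%; the acceptance conditions use 0 so
  that exact-recovery claims are well-defined. An insertion's body is
  drawn once and shared by all accessions carrying it.
* **Fragmentation** truncates 10–60% of a copy from one end; truncated
  copies keep their TSDs (decay-after-insertion model) and are excluded
  from the intact truth set.
* **Derived accessions** drop each insertion independently with
  `absence_prob`, restoring the exact pre-insertion background (single
  TSD copy). Coordinates for every genome are tracked in the truth
  registry.
* **Transcripts**: full-element transcripts are copies of intact planted
  bodies (round-robin over families); TE-bearing genes take a
  single-exon model whose exon crosses an element boundary so that a
  120 bp element fragment falls entirely in the CDS, 5′ UTR or 3′ UTR;
  every third clean gene gets a second (background) exon to exercise
  the projection; clean genes are verified to share no 20-mer with any
  family reference. TE-bearing genes are generated on the plus strand;
  minus-strand handling is exercised by clean genes and unit tests.

All generator operations are deterministic given their seed (the test
suite asserts byte-identical FASTA).

## 8. Problem sizes and numerical choices

The discovery-scale simulation used by the acceptance tests and script
is a 2-chromosome, 2-Mb genome with 5 families × 10 copies
(fragmentation 0.3) and three derived accessions at `absence_prob`
0.1 — large enough that every family has intact and truncated copies
and every accession draws absences, while the full suite runs in well
under two minutes. Alignment DP matrices are int32; banded traceback
recomputes gap jumps from the score matrix rather than storing pointer
planes. Degenerate inputs are errors, not silent results: empty FASTA,
duplicate ids, non-ACGTN characters, intervals off chromosome ends,
CDS outside exons, elements spanning a whole chromosome.

## 9. Known limitations

* Boundary exactness is guaranteed only at zero divergence; terminal
  mutations can trim detected repeats and make an intact copy fail the
  strict TSD+terminal gate (a missed call, never a shifted boundary).
* When a transcript covers only part of an element, the boundary
  proposal comes from the multi-copy union, whose jitter window (±5 bp)
  must contain the true boundary; single-copy partially-transcribed
  elements without internal terminal structure are not definable.
* No nested insertions, no PBS/PPT or ORF-domain annotation, no
  composition-adjusted alignment statistics, no HSP chaining across
  introns; one-directional comparison only (insertions present in the
  reference and absent elsewhere, not the reverse).
* The uniqueness margin (2 identity points) operationalizes "multiple
  hits with the same identity"; flanks duplicated at lower identity
  than that margin will be called UNIQUE.
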