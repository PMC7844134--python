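# Methods

This note documents the models, parameter choices and limitations behind
`gemmapgc`, in the order the pipeline runs.

## Genome model and coordinates

Internally every feature is 0-based half-open on its contig; GFF3 on disk
is 1-based inclusive and converted at the boundary.  This makes interval
arithmetic closed under splitting and concatenation and removes the `+1`
class of bugs from window and fragmentation code.  Features without a
protein (RNA genes, pseudogenes) are retained but invisible to homology
search.  Presence tables use the typography of printed tables: `+`
present, `−` (Unicode minus) or `-` absent, blank unknown.

## Family search

* **Engine.** Smith–Waterman local alignment over BLOSUM62 with affine
  gaps, open 11 / extend 1 (a gap of length k costs 11 + k).  The
  implementation is `Bio.Align.PairwiseAligner`; the test suite holds its
  raw scores equal — exactly, not approximately — to an independent
  pure-Python dynamic-programming oracle.
* **Significance.** Karlin–Altschul: `bit = (λS − ln K)/ln 2`,
  `E = m·n·2^(−bit)` with the standard gapped parameters λ = 0.267,
  K = 0.041, `m` the query length and `n` the summed reference length.
  Exact E-values differ between alignment engines; the cutoffs
  (`E < 1e−5`, coverage > 0.40) are the normative part, and both are
  strict inequalities.
* **Coverage** is measured against the reference protein length, because
  the rule screens for homolog completeness relative to the known gene.
* **Best-family choice**: highest bit score, ties broken by identity, then
  lexicographic family name; at most one assignment per locus.
* **Split genes.** Two same-family sub-coverage hits on one contig within
  3 kb are merged when their combined coverage clears the cutoff, and
  flagged `split`.  The same merge applies to same-family truncated hits
  stranded at the ends of *different* contigs (assembly breakpoints cut
  genes; the pieces surface at contig termini).  Circular contigs have no
  termini and are exempt from the edge rule.
* **Reference set.** One representative protein per family.  The shipped
  set is synthetic: deterministic pseudo-random proteins of realistic
  length and composition (`source="synthetic"` in the FASTA headers).
  Because the simulator derives every planted protein from this same set,
  the statistical behaviour of search, thresholds and recovery is
  exercised exactly as with curated references; a production deployment
  would drop in curated proteins via `reference_fasta` without code
  changes.  Identity values against synthetic references mean nothing for
  real genomes — that is the one thing passing tests do *not* show.

## Cluster chaining

Defaults: `max_gap` 6 kb, `max_intervening` 5, `min_members` 4.  A ~42 kb
cluster of ~30–40 genes implies sub-kilobase intergenic gaps; 6 kb
tolerates the hypothetical-ORF stretch between the puh and puf operons
while not bridging distant scattered genes, and `min_members` 4 suppresses
"clusters" formed by isolated crt/hem genes in background genomes.  All
three are configurable and must be: no numeric chaining criteria exist in
the literature for this cluster family.  On circular contigs the first and
last chains are merged when they satisfy the same gap/intervening rules
across the origin, so cluster recovery is invariant to origin rotation.
Increasing `max_gap` merges chains and can only reduce the raw chain
count; note the `min_members` filter can then re-admit a merged chain, so
the monotonicity statement applies at chain level.

Cluster continuity is probed by the three positionally flexible anchor
genes acsF, bchO and puhE: a genome's cluster set is *continuous* when one
single candidate contains all three.  puhE is deliberately treated as a
singleton anchor rather than a member of the lhaA-puhABC sub-cluster.

## Architecture

The gene→sub-cluster table is the single source of truth:
bchP2G = {bchP, idi, bchG}, bchFNBHLM = {bchF, bchN, bchB, bchH, bchL,
bchM}, lhaA-puhABC = {lhaA, puhA, puhB, puhC}, pufBALMC = {pufB, pufA,
pufL, pufM, pufC}, crtF-bchCXYZ = {crtF, bchC, bchX, bchY, bchZ},
bchID = {bchI, bchD}.  Segmentation takes maximal runs of same-sub-cluster
genes; unlabelled (hypothetical) genes are transparent; non-canonical
genes become singletons.  Block orientation is the majority strand (ties:
first member), and the whole signature is canonicalized to the majority
reading direction, which makes segmentation invariant under a uniform
strand flip plus coordinate reversal.

The placement markers ask whether the acsF singleton lies between the
bchFNBHLM and lhaA-puhABC blocks (either reading direction, no other
canonical block in between), and analogously bchO between pufBALMC and
crtF-bchCXYZ.  A missing singleton or flank makes the marker false and is
recorded in `missing`.

Architecture distance = unsigned breakpoints between the shared-block
orders + shared blocks with differing orientation + blocks private to one
signature.  It is symmetric and zero exactly on identical signatures; the
triangle inequality is *not* guaranteed and not asserted.  The distance
definition itself is a design choice of this package — the underlying
biology only states that no proteobacterial cluster matches the
Gemmatimonadetes arrangement.  The packaged proteobacterial reference
architectures are synthetic stand-ins encoding plausible per-class
permutations (their names carry the `-synthetic` suffix), not
transcriptions of deposited genomes.

## Classification

* CGB: puf, puh and bch categories all present; `unknown` counts as
  absent (conservative inclusion).
* Oxygen: aerobic-indicated iff bchE absent and BphP and BphO present;
  microaerophilic-indicated iff bchE present; otherwise indeterminate.
  `unknown` cells are not evaluable as absences.  When genome completeness
  is below 75%, any call that leans on an absence downgrades to
  indeterminate — a missing gene in an incomplete MAG is weak evidence.
  The output is an *indication class*, never a physiological claim.
* Taxonomy: ANI ≥ 96% → same species; ANI < 95% → different species, with
  16S deciding the genus (> 95% → same genus, ≤ 95% → new genus
  candidate; no 16S value → the genus is retained, since a new genus
  cannot be proposed without 16S evidence).  ANI inside [95, 96) returns
  "conflicting evidence" unless 16S corroborates a side (≥ 98.7% → same
  species; in (95, 98.7) → new species same genus).  The band endpoints
  are not collapsed to a point cut because the convention itself is a
  band.

## Pairwise comparison

Protein identities come from global alignment with terminal gaps trimmed;
the denominator is alignment columns including internal gaps.  The >90%
high-identity flag is strict.  Split genes are represented by their
longest fragment.

Synteny blocks: exact 11-mer anchors on both strands, grouped by diagonal
(±30 bp drift) and chained across gaps ≤ 300 bp; chain ends are extended
ungapped with an X-drop criterion (match +1, mismatch −2, X = 12); block
identity is recomputed over the paired spans by edit-distance alignment
(edlib).  Blocks must strictly exceed the dialect cutoffs (cluster
dialect: 70% / 500 bp; genome dialect: 80% / 2 kb) and are made
non-overlapping on the first sequence, longest first.  Anchoring with
k = 11 loses sensitivity below roughly 75% nucleotide identity; that is
above both dialect cutoffs' intended use (conserved-region plotting), and
the planted-island tests bound the boundary error at ±50 bp.

## Simulation

The generator's defaults are the study conditions the package is tested
under: the Gemmatimonadetes-type template (33 genes including three
hypothetical ORFs between the puh and puf operons), intergenic gaps
uniform in 50–500 bp, 10 background genes, and two marker genes (BphP,
BphO) planted outside the cluster so that the default genome emulates an
aerobic chlorophototroph; bchE is never planted.  Default planted-protein
identity is 0.75 versus the references — comfortably inside the
significance regime but far from trivial self-hits.

* **Mutation model**: residue substitutions at positions sampled without
  replacement, replacements drawn from the BLOSUM62-positive exchange set
  of the original residue; no indels by default.  Substitution-only
  mutation makes the realized global identity exactly `1 − k/L`, so
  identity targeting is exact to rounding (±2 percentage points is the
  guaranteed envelope) and alignment oracles stay simple.
* **Back-translation**: bacterial codon table 11, uniform synonymous
  choice from the seeded generator; background composition at 65% GC.
* **Background ORFs** (200–1500 codons) and hypothetical ORFs (80–200
  codons) are rejection-sampled to be non-significant against the full
  reference set — a built-in false-positive control.
* **Fragmentation**: `n_contigs − 1` uniform breakpoints; pieces are
  retained in random order, stopping at the prefix whose cumulative
  length is closest to the completeness target (which keeps the retained
  fraction unbiased, ±half a piece per replicate).  Genes cut by a
  breakpoint are annotated on both sides with in-frame truncated proteins
  when at least 15 residues survive.  A planted gene counts as retained
  when at least half its length survives.
* **Planted splits**: `split_genes` plants a family as two partial CDS of
  38% of the protein each — individually below the coverage threshold,
  jointly above it — exercising the split-gene merge exactly as a
  fragmented MAG annotation would.

What the simulator does not emulate: real intergenic signal (spacers are
random DNA), operon-level transcription structure, codon bias,
sequencing or binning error, contamination, and real reference proteins.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic and thresholds under the stated statistical conditions,
not field performance on environmental MAGs.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic or
packaged desk-scale inputs: simulated genomes of ~70 kb with 45 genes,
50 recovery replicates in the suite and 10 in the acceptance script,
200 and 100 fragmentation replicates respectively, and 100 random pairs
for the exact score-oracle comparison.

## Known limitations

* E-values are calibrated to BLAST's gapped parameters but computed on a
  query × reference-set search space; absolute values differ from any
  specific BLAST invocation.  Only the thresholded decisions are stable
  across engines.
* The architecture distance treats duplicate blocks by first occurrence;
  tandem-duplicated sub-clusters would need a richer encoding.
* Synteny block finding is not a whole-genome aligner; multi-megabase
  comparisons and large-scale rearrangement inference are out of scope.
* ANI/AAI and 16S identities are consumed as inputs, never computed here.
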