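# Methods

This note records the models and procedures phamkit implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic studies do and do not demonstrate.

## Coordinates and I/O

All coordinates are 0-based half-open on the forward strand internally;
GenBank and GFF3 1-based inclusive conventions are converted only at the
I/O boundary. Sequences containing characters outside {A, C, G, T} are
rejected rather than masked: an ambiguity code disqualifies the genome,
which keeps every downstream identity count exact. tRNA/tmRNA features
are retained as genome metadata but excluded from the gene list, because
every similarity metric here is defined on protein-coding genes.

The de novo ORF caller is a transparent stand-in for production gene
callers: maximal ORFs in six frames, starts {ATG, GTG, TTG}, stops
{TAA, TAG, TGA} (translation table 11), longest ORF per stop codon, no
ribosome-binding-site scoring. The floor is 30 amino acids by default
(phage genomes carry many genuinely small genes; lower floors admit
mostly noise ORFs). Circular genomes can be rotated so that a designated
plus-strand anchor gene (conventionally the terminase) starts at
coordinate 0; rotation to a minus-strand anchor is undefined and raises,
as is rotation that would split a gene across the new origin.

## Pham assembly

Proteins are compared by global alignment (BLOSUM62, gap open −11,
extend −1, via Bio.Align.PairwiseAligner). Identity is identical aligned
positions over alignment columns excluding terminal gaps; X never counts
as a match. Coverage is the aligned span of the shorter sequence over
its length. Arguments are aligned in a canonical order so the function
is exactly symmetric even when optimal alignments are degenerate.

Edges join pairs with identity ≥ `min_identity` (default 0.35) and
coverage ≥ `min_coverage` (default 0.80); phams are connected components
(single linkage), since phamily membership is a transitive notion — a
chain A~B~C belongs together even when A and C have drifted below the
pairwise threshold. Component ids are assigned deterministically
(ordered by smallest member key, numbered from 1), so pham ids are
stable under input permutation.

The k-mer Jaccard prefilter trades alignment work for a small risk of
missed edges. Defaults are k = 4 and Jaccard ≥ 0.005: a pair at the 35%
identity floor shares roughly 0.35⁴ ≈ 1.5% of its 4-mers (Jaccard
≈ 0.01, twice the gate), while unrelated ~100-aa proteins sit near
0.0006, an order of magnitude below it. A 5-mer filter at Jaccard 0.05
— superficially attractive — silently discards genuine 35–50% identity
relationships, which is exactly the regime the identity threshold is
meant to capture. Setting `min_kmer_jaccard = 0` disables the prefilter
entirely; the test suite verifies that the filtered and unfiltered
partitions agree on representative datasets.

## Similarity metrics

**GCS** averages the two directed shared-gene fractions, the only
direction-symmetric reading of "how many genes of the same phamily are
shared".

**Homologue pairing.** Within each pham shared by two genomes, member
genes are paired greedily by descending alignment identity, ties broken
by gene id; leftover paralog copies stay unpaired. The pairing choice
only matters when paralogs exist, and a greedy matching is deterministic
and cheap.

**PEQ** is the length-weighted identity quotient

    PEQ = 100 · Σ_pairs (len_a + len_b) · identity / Σ_all genes len,

with the pair weight `len_a + len_b` chosen so that identical proteomes
give exactly 100 and every unshared gene drags the value down with its
full length. This is the simplest single value that combines
shared-gene proportion with amino-acid identity and behaves correctly
at both extremes (100 iff identical under the pairing; 0 iff no shared
pham). The formula is isolated in one function (`phamkit.metrics.peq`)
so an alternative normalization can be swapped in without touching
anything else. **AAI** is the same weighted mean restricted to the
paired homologues (no penalty for unshared genes).

**HSP search** is ungapped seed-and-extend on both strands: exact
11-mers seed two-way X-drop extensions scored +1/−2 (X-drop 20),
overlapping extensions on a diagonal merge greedily, and HSPs contained
in a higher-scoring HSP are dropped. E-values follow Karlin–Altschul
E = K·m·n·e^(−λS) with the classic ungapped +1/−2 parameters λ = 1.28,
K = 0.46. The E-value is a filter (default ≤ 1e−4), not a reported
statistic, so modest parameter error only perturbs borderline HSPs.
E-values are floored at 1e−300 to stay positive under long perfect
hits. Word size 11 and X-drop 20 are conventional ungapped nucleotide
defaults; both are exposed.

**gNI** runs the HSP search in both query/subject roles, projects all
segments onto each genome, and resolves overlaps by taking fragments in
decreasing identity-fraction order, pro-rating a segment's identities
over whatever part of it is not yet claimed. Identical bases are then
normalized over both genome lengths: gNI = 100·(id_a + id_b)/(len_a +
len_b). The sum/sum normalization keeps gNI ≤ 100 under duplications
(a min-length normalization would not). Pro-rating is an approximation
only where HSPs overlap, which the E-value filter makes rare on
non-repetitive genomes; self-comparison still yields exactly 100.

## Clustering

Clusters are connected components of the thresholded similarity graph —
the parameter-free closure of a pairwise-edge criterion, and the
metric-agnostic backend works identically for PEQ and gNI matrices.
Default thresholds: 25 (PEQ) for clusters, 60 (PEQ) for subclusters.
Components are ordered by size (descending) then smallest member id and
lettered A…Z, AA…; singletons carry the distinct label "singleton"
rather than consuming letters. Subclusters exist only where the
stricter threshold actually splits a cluster. Because raising the
threshold can only remove edges, the partition at a higher threshold
refines the partition at a lower one, and the cluster-count curve is
non-decreasing — both properties are asserted in the tests.

## Taxonomy

Ranks (species < genus < subfamily < family) form a tree, so
co-membership at a low rank implies co-membership above. Gap-filling
walks rank pairs bottom-up: a named taxon missing its parent first
inherits any parent named by a co-member, otherwise receives the
deterministic placeholder `unnamed_<rank>_<taxon>`. Given names are
never overwritten; a taxon under two different named parents is a
consistency error. The operation is idempotent, and placeholders chain
upward so intra-rank pair sets nest species ⊆ genus ⊆ subfamily ⊆
family. Genomes with no named rank at all contribute no intra-rank
pairs anywhere. Pairs are unordered and self-pairs excluded; "no
detectable similarity" is encoded as exactly 0 after E-value filtering.
Histograms use width-5 bins [0,5), [5,10), …, [95,100] (the last bin
closed); the width is an implementation choice.

## Maps

SVG was chosen over raster output so tests can assert fill colors and
geometry textually. Pham colors come from a fixed 28-color palette
indexed by the MD5 of the pham id — deterministic across runs and
machines, unlike Python's salted `hash`. Orphams are always white.
Similarity shading maps identity fraction linearly onto hue: 1.0 →
270° (violet) down to 0° (red) at the lowest identity passing the
E-value filter anywhere in the figure; if all segments are equally
similar, everything is violet. Zoomed views reuse the same renderer
with a coordinate window rather than a separate code path.

## Synthetic data

The simulator emulates the mosaic structure the metrics are built for:
clusters draw from disjoint pham pools; genomes within a cluster share a
core fraction (default 0.8) of a repertoire (default 30 phams/genome)
and sample accessory phams per genome; horizontal transfer inserts
foreign-pool genes at a Poisson rate (default 1/genome). Proteins
diverge from their phamily ancestor by iid uniform substitutions
(default 0.05/site within a cluster level; 0.25 between subcluster
ancestors when two-level structure is requested — calibrated so
intra-subcluster PEQ sits near 75–85, cross-subcluster near 45, and
cross-cluster near 0, i.e. clean margins around the 25/60 thresholds).
Gene lengths are normal (mean 200 aa, sd 40, floor 50); genes are laid
head-to-tail with fixed 50-bp random spacers.

Nucleotide sequences are produced by back-translating each ancestral
protein once with uniform synonymous codon choice; genomes inherit
those codons, amino-acid substitutions re-draw the affected codon, and
`nt_divergence` (default 0.02/site) adds substitutions accepted only
when synonymous. Two consequences are deliberate: (i) with every rate
at zero the genomes of a cluster are byte-identical (each phamily's
spacer and strand are drawn once and travel with it), and (ii) a gene's
stored translation always equals the translation of its CDS, so written
FASTA+GFF3 round-trips exactly. Because codons are inherited rather
than re-drawn per genome, nucleotide identity between relatives tracks
amino-acid identity closely at low divergence; the regime where
nucleotide similarity is undetectable while protein similarity remains
(low gNI, positive PEQ) appears at per-lineage divergences around
0.4–0.5, which is where the divergence-sweep checks operate.

All randomness flows through a single numpy PCG64 generator
(`numpy.random.default_rng(seed)`), so a spec plus seed reproduces a
dataset byte for byte across platforms.

What the simulator does **not** model: insertions/deletions within
homologues, substitution-matrix-structured amino-acid exchange,
recombination breakpoints, selection, gene loss along a phylogeny,
prophage/host context, or annotation noise (every gene is called
exactly). Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline under clean mosaic structure, not
performance on real, messily annotated genomes. Indel robustness of the
aligner is exercised separately with hand-built cases.

## Problem sizes

The test and acceptance studies use deliberately small instances chosen
to exercise every code path: 12–20 genomes of 8–12 genes at 90–150 aa
(genomes of roughly 3–7 kbp), 200 proteins for the all-pairs pham
oracle, 2-kbp sequences for the quadratic alignment oracle, and a
divergence sweep of 8 levels × 6 pairs. These sizes keep the whole
suite in the tens of seconds while remaining large enough for the
statistical checks (binomial bounds, 3-sd windows, rank correlations)
to be meaningful.

## Known limitations

- The ORF caller ignores RBS context and overlapping genes in the same
  frame sharing a stop; it is not a substitute for a trained gene
  finder.
- PEQ depends on annotation uniformity: a gene annotated in one genome
  but not its twin lowers PEQ even when the sequences are identical.
  gNI is insensitive to annotation and is the better metric for very
  similar pairs.
- The E-value parameters are fixed ungapped constants; values near the
  1e−4 boundary should not be over-interpreted.
- gNI overlap resolution pro-rates identities across overlapping HSPs
  instead of recomputing per-base, a negligible approximation away from
  repeats.
- Cluster letters follow the de novo partition only; historical letter
  assignments of named collections are out of scope.
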