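# Methods

## Scope and data model

The package analyzes an annotated multi-replicon genome for signatures of
reductive evolution. All intervals are 0-based half-open internally;
1-based inclusive coordinates exist only at the GFF3 boundary
(`start_internal = start_gff − 1`). Ambiguity codes collapse to N on read;
N translates to X and never scores as a match or a stop. Minus-strand
features are reverse-complemented lazily on extraction and never stored
reversed.

## Pseudogene calling

**Evidence model.** Each candidate CDS is extended by 90 nt on each side
(so truncation is measured against alignment evidence, not annotation
edges) and aligned locally, in each of its three forward-strand frames,
against candidate reference proteins (BLOSUM62, gap open −11 / extend −1;
bacterial genetic code, table 11, TGA = stop). Candidate references are
shortlisted by shared amino-acid 5-mers (top 3) before alignment; the best
reference is the one with the highest chain score, ties broken by longer
reference then lexicographic id.

**Block decomposition.** A local aligner with cheap gap extension will
bridge two strong matches across a stretch of out-of-frame translation,
because random amino-acid pairs average only about −0.5 under a log-odds
matrix. Each raw alignment is therefore re-scored column-wise and cut
(i) wherever an 11-column window falls below 30% identity, (ii) at gaps of
≥ 4 residues, and (iii) wherever the running score drops more than 25
below its maximum (X-drop / HSP decomposition). Surviving segments are
trimmed to start and end on a run of ≥ 3 consecutive exact matches and
kept if they score ≥ 40. Premature stop codons inside a block are counted
and scored as mismatches; they never terminate a block. The identity-based
cuts assume candidate and reference are close homologs (the regime the
package targets, where the reference set derives from the genome's own
lineage); for distant homologies they would fragment legitimate alignments.

**Chaining.** The maximum-score chain of blocks collinear in both region
and reference coordinates is found by DP; each frame change between
consecutive blocks costs −15, and boundary overlaps up to 36 nt / 12 aa
(alignment fuzz around an indel) are tolerated but charged at −4 per
overlapping residue so clean junctions win. The chain yields
`n_frameshifts` (frame changes), `n_stops` (summed block stops) and
`aligned_fraction` (covered reference residues ÷ reference length).

**Rules.** Pseudogene iff `n_stops + n_frameshifts ≥ 2` (threshold
configurable; the "more than one stop codon or frameshift" reading —
tolerating a single interruption as a possible sequencing or annotation
artifact), or `aligned_fraction < 0.30` with a nonempty chain, or the
split rule fires. Class labels: stops > frameshifts → `internal_stop`;
otherwise `frameshift`; coverage rule → `truncated`; split rule →
`split`. The truncation fraction is measured on the reference protein's
coordinates, not the candidate's nucleotides, and against the best-hit
protein's length (profile lengths are not modeled). A CDS with no homolog
at all is left intact and flagged `no_evidence`.

**ORF-split detection.** Two same-strand features within 5 kb whose best
hits are near-disjoint segments (reference overlap < 20% of the shorter)
of one reference protein, in genome order consistent with reference order,
with ≥ 1 intervening annotated ORF of a different product, are flagged as
one split event. The split label wins over per-fragment verdicts so both
halves group under one event id.

## IS-remnant detection

**Repeat families.** 16-mers occurring ≥ 3 times (over the forward and
reverse-complement views of every replicon, so copies in either
orientation count) seed greedy bidirectional consensus extension. A copy
is dropped when its mismatches exceed 20% of the extended length;
extension stops when fewer than 3 copies survive or when agreement over
the last 30 columns falls below 80% (this recent-agreement window is what
halts extension at element boundaries, where flanks are unrelated).
Consensi < 600 bp are discarded; copies are then relocated genome-wide by
the homology scanner and families whose copy sets largely coincide
(a family and its own reverse complement) are deduplicated.

**TIRs.** For offsets up to 50 bp from each end, a two-pointer walk finds
the longest prefix/suffix pair with left = revcomp(right) up to 2
mismatches, minimum 10 bp; ties break longest, then outermost.

**Homology scan.** Exact 11-mer seeds between genome and library are
extended ungapped with an X-drop of 20 under +1/−2 scoring; co-diagonal
neighbouring extensions within 30 bp are chained with affine gap charges
(−5 open, −2 extend). Bit scores use fixed Karlin–Altschul constants
(λ = 1.33, K = 0.621 for +1/−2): S = (λ·raw − ln K)/ln 2 and
E = m·n·2^(−S) with m the total genome length and n the total library
length. These constants are approximations; E-values are comparable within
a run, not across tools. Hits with E ≥ 10⁻⁵ are discarded.

**Merging into distinct sites.** Fragments of one library sequence on one
replicon and strand merge when the inter-fragment gap is ≤ 3000 bp (the IS
length ceiling) and their library coordinates are non-overlapping and
ordered along the element; re-covering the same library interval signals
two independent insertions and blocks the merge. Two post-passes make the
site count robust: (i) remnants overlapping by > 50% of the shorter (the
same locus described by a user library hit and a de-novo family, or by the
two strand readings of a near-palindromic element) collapse to one;
(ii) two families that sit adjacent within the merge window at ≥ 2
independent loci are read as two parts of one element (de-novo discovery
splits a family when some copies are themselves fragmented) and their
adjacent remnants unify. Both the distinct-site count and the raw fragment
count are reported. The merge is idempotent.

**Transposase census.** ORFs (start ATG/GTG/TTG to in-frame stop, ≥ 50
codons, both strands) overlapping each merged site are counted; those
> 200 aa are "long" (potentially functional). A site whose longest ORF
spans ≥ 80% of its family consensus is `intact_transposase`, else
`fragmented`.

## Erosion statistics

GC is 100·(G+C)/(A+C+G+T) with N excluded from the denominator. The coding
fraction counts the union of intact CDS intervals once; pseudogenes are
excluded. The genome-wide pseudogene percentage uses all genes (intact
CDS + RNA genes + pseudogenes) as denominator. The per-replicon erosion
ratio is pseudogenes : predicted genes with predicted genes = intact CDS +
RNA genes by default (pseudogenes excluded from the denominator); a
CDS-only variant is reported alongside because annotation conventions
differ on whether RNA genes count as predicted genes. Percentages print at
one decimal; JSON keeps full precision.

## COG enrichment

The contingency table is categories × {intact, pseudogene}; genes without
a category are excluded and counted separately; a gene listing several
categories keeps the first. The Pearson statistic Σ(obs−exp)²/exp is
tested with a Monte-Carlo simulated p-value: the null redistributes the
pseudogene labels uniformly over genes within fixed category sizes
(multivariate hypergeometric — a label permutation conditioning on both
margins; the test names only the statistic, so the conventional
simulated-p sampling scheme is adopted), and p = (b+1)/(B+1) with b the
replicates at least as extreme. The add-one estimator is never zero and
has floor 1/(B+1) — at the default B = 2000, 1/2001 = 0.0004998.
Per-category Pearson residuals (obs−exp)/√exp are reported for the
pseudogene column; Σ over all cells of residual² equals the statistic
exactly.

## Gene-set comparison

Each entry of a curated set is aligned (same chain machinery) against
every annotated coding region; matches with chain score ≥ 50 inherit the
feature's call. Any intact match anywhere overrides pseudogene matches
elsewhere — a plasmid-borne pseudogene with an intact chromosomal
counterpart counts as intact — making the verdict order-independent. No
match at all → absent. Best-reciprocal-hit pairing reports (a, b) iff each
is the other's highest-scoring local alignment, ties broken by id order.

## Synthetic genomes

The generator emulates an eroding endosymbiont genome: three replicons
(120 / 20 / 10 kb chromosome + two plasmids by default), genome GC 38.3%,
100 genes back-translated from a reference proteome, 31.2% of genes
pseudogenized, and 12 IS insertions (700–3000 bp, 20-bp TIRs) in 3
families with 30% of copies fragmented. Codons are sampled from the iid
base distribution at the GC target conditioned on the encoded residue —
GC is the only compositional property the downstream statistics touch, so
no organism-specific codon-usage table is modeled. Intergenic spacers are
iid at the GC target. COG labels are uniform over the 21 categories;
pseudogene membership is drawn with odds multiplied per category
(default skew: L ×4, Q and B ×2, T and S ×1.5 up; H ×0.4, J ×0.3, M ×0.5
down — the qualitative over/under-representation pattern expected in a
degrading genome where mobile-element and regulatory functions decay
first while translation and envelope biogenesis are preserved). The class
mix is 30% internal-stop, 30% frameshift, 20% split, 20% truncated —
chosen once as a roughly even spread that exercises every calling rule.

Planted events are constructed, not simulated: internal stops replace ≥ 2
interior sense codons; frameshifts are ≥ 2 indels of 1–2 bp at codon
boundaries, ≥ 15 codons apart (two indels so the planted class
unambiguously crosses the "more than one interruption" threshold;
single-interruption genes are built only in boundary tests); splits insert
a back-translated intervening ORF of ≥ 150 bp mid-gene (the two halves and
the insert are annotated as three CDS features); truncations keep a prefix
of 18–29% (29%/31% pairs probe the threshold in the boundary tests). IS
sites of one genome are kept > 3.1 kb apart so distinct sites are
unambiguous under the 3-kb merge window. Every event carries a TruthRecord
whose defining property is re-verified from the emitted sequence in the
test suite. A single seeded numpy Generator drives all randomness;
identical (config, seed) gives byte-identical output.

What the generator does **not** emulate: sequence divergence between a
gene and its reference (alignments are near-identity), organism-specific
codon usage, degraded or nested mobile elements, overlapping genes, and
real annotation noise. Passing the recovery suites therefore shows the
rules and plumbing are correct under clean evidence, not that the caller's
sensitivity transfers to diverged real annotations.

## Problem sizes and numerical choices

Default test conditions run one 150-kb three-replicon genome with 100
genes and 12 IS copies (about 10 s for the full suite's shared fixtures);
the GC-target check uses a single 500-kb replicon. Monte-Carlo checks use
B = 2000 (the default) and B = 10⁵ against exhaustive enumeration on an
8-gene table. Ties everywhere break deterministically (score, then length,
then lexicographic id); all stochastic stages take an explicit seed, and
the pipeline writes its resolved config and output digests so a run can be
reproduced byte-for-byte.

## Known limitations

Only the annotated strand's three frames are searched; reverse-strand
evidence for a stranded feature is out of scope. Profile (COG/Pfam)
truncation is approximated by best-protein coverage. The homology scanner
is seed-and-extend with fixed approximate Karlin–Altschul constants, not a
full Smith–Waterman, and its E-values are internal. De-novo repeat
discovery needs ≥ 3 same-orientation-recoverable copies ≥ 600 bp; a family
whose surviving copies cannot assemble a 600-bp consensus is found only
via the IS library. IS family taxonomy and target-site duplications are
not modeled.
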