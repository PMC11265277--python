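# Methods

## The pair synteny graph and similarity measure

Two genomes A and B are modelled as ordered gene lists (ranks 1..N, taken
from the GenBank flat-file order, concatenated across replicons in file
order). An ortholog set links genes of A to genes of B; the measure requires
at least two ortholog pairs, and genome pairs below that threshold are
recorded as missing (zero) in the pairwise matrix rather than scored.

Bacterial chromosomes are circular, so the flat-file order is one arbitrary
reading among N. The measure therefore evaluates 1 + n arrangements for n
ortholog pairs: the original order, plus one arrangement per ortholog pair
in which both genomes are circularly rotated so that the pair's genes take
rank 1 (all other genes keep their cyclic order). Within an arrangement,
every unordered combination of two ortholog pairs {i, j} contributes

    cos(u, v),  u = (rank_A(i), rank_A(j)),  v = (rank_B(i), rank_B(j)),

aggregated by the mean over all C(n, 2) combinations; the final similarity
is the median over arrangements (even counts take the midpoint of the
central pair). Ranks are strictly positive, so every cosine — and hence the
similarity — lies in (0, 1].

Properties the test-suite asserts: symmetry in (A, B); exact invariance to
circular rotation under full orthology; invariance of each cosine to
uniform scaling of one genome's ranks; monotone degradation in expectation
with transposition count; and exact agreement (1e−12) with a brute-force
enumerator on genomes of ≤ 6 genes.

### Choices where the design was genuinely open

- **Cosine vector construction.** Pairing within-genome position vectors
  across genomes (`genome-vectors`, the default) is scale-invariant per
  genome and treats "similar ortholog positions" literally; the alternative
  `ortholog-vectors` pairing (u = (rank_A(i), rank_B(i)) vs
  v = (rank_A(j), rank_B(j))) is available as a configuration switch.
- **Within-arrangement statistic.** Mean by default, median available.
  Both are exposed because they answer slightly different questions (the
  median damps single badly displaced orthologs).
- **Rank basis.** Ranks run over the full gene order by default; an option
  restricts ranking to orthologous genes only, which makes the measure
  independent of unshared gene content.
- **Many-to-many hits** are reduced to a one-to-one mapping greedily by
  best identity (ties: longer alignment, then lexicographic gene ids); a
  pivot needs exactly one partner per genome.
- **Strand is ignored** throughout; the measure sees positions only.
- Numerically, each cosine is computed as dot/√(‖u‖²·‖v‖²) with a single
  square root so that identical rank vectors score exactly 1.

## Synteny coverage

Coverage of genome A by a pair's shared blocks = (summed shared block
length) / (total length of A); asymmetric by construction. When per-gene
coordinates are available, physically overlapping blocks are merged (union
length) so a fully tiled genome scores exactly 1; otherwise aligned block
lengths are summed as reported.

## Sketch distances

A self-contained bottom-s MinHash sketcher replaces external sketching
binaries: canonical k-mers (lexicographic min of k-mer and reverse
complement; windows containing N skipped) are hashed by a seeded
splitmix64-style 64-bit mixer over the 2-bit encoding (a keyed blake2b path
covers k > 31), and the s smallest distinct hashes form the sketch.
Defaults k = 21, s = 1000 — the customary sketching defaults. The Jaccard
index is estimated from the merged bottom sketch (exact when the input has
≤ s distinct k-mers — asserted against a set-arithmetic oracle) and
converted to d = −(1/k)·ln(2j/(1+j)), clamped to 1 at j = 0 where the
formula diverges. Multiple marker-gene copies per genome (e.g. several 16S
genes) are compared over all cross pairs and aggregated by mean (default)
or min; whole genomes pool replicons into a single sketch.

## Matrix augmentation

Distances are 1 − similarity, applied verbatim to missing entries (so a
missing similarity becomes distance 1). The augmented matrix is
M = D_16S · cov(D_syn) with covariance over columns (denominator n − 1,
configurable), min–max normalized over all entries (a constant product maps
to the zero matrix), symmetrized as (M + Mᵀ)/2, and the diagonal forced to
0 last so that self-distance is always "completely similar". The product of
two symmetric matrices is not symmetric in general, which is why the
symmetrization step is explicit; the largest pre-symmetrization asymmetry
is logged. Normalization order (before diagonal forcing) is a convention of
this package.

Sparsity reductions: **Thr** keeps entries strictly above 82 % similarity
(the reporting floor of modern ANI tools; applied on the similarity scale,
distance-scale matrices are converted and back); **Rem** keeps the
positions that are non-zero in a reference (ANI) matrix. Zero always
encodes "missing" in these sparse matrices; `sparsity` is the fraction of
zero entries among n².

## Clustering evaluation

Complete-linkage agglomerative clustering (scipy) on the pairwise distance
matrix, with the *cluster cutoff* interpreted as the requested number of
flat clusters (maxclust), swept over an integer axis. Missing entries are
filled with the maximal distance 1 before clustering — sparse matrices
otherwise have no defined dissimilarity — and that fill is logged whenever
it fires. Silhouette uses the precomputed-distance formula
mean((b − a)/max(a, b)) with two conventions: singleton clusters score 0,
and a = b = 0 scores 0; it is cross-checked against scikit-learn and a
textbook implementation. The Rand index is the plain (unadjusted) pair
agreement fraction in [0, 1]. Dendrograms export to Newick with merge
heights as branch lengths.

## Graph comparison

KNN graphs are built per node by k-nearest selection on the distance matrix
(ties broken by label order), union-symmetrized — so degrees may exceed k —
with edge weights equal to the distances, globally max-normalized to
[0, 1]. Comparisons between graphs on the same genomes:

- Newman modularity of a supplied partition (taxonomy labels when given),
  unweighted by default with a weighted variant behind a flag;
- Jaccard and Dice over edge sets, and weighted Jaccard
  Σ min(w₁, w₂)/Σ max(w₁, w₂) over the edge union (absent edge = 0);
- DeltaCon: node affinities S = (I + ε²D − εA)⁻¹ from linearized belief
  propagation (ε = 1/(1 + max degree) by default; unweighted adjacency by
  default), compared by the Matusita distance
  d = √Σ(√S₁ − √S₂)², reported as the bounded similarity 1/(1 + d) rather
  than the unbounded 1/d. Node attribution is the per-row root-Euclidean
  distance; edge attribution assigns each edge present in exactly one graph
  the sum of its endpoints' node attributions, negative for removals.
  The production solve is checked against a dense-inverse oracle to 1e−8.
- Girvan–Newman: exact edge-betweenness recomputation after every removal
  (O(VE) per step, fine at a few hundred genomes); the reported partition
  is the split level with maximum modularity, with the input's component
  partition as level 0 so the choice never scores below the trivial Q = 0.

## Functional cohorts

All cohorts share two filters: database hits with identity strictly above
90 %, and ortholog hits with identity strictly above 95 % and aligned
length in [500, 2500] bp inclusive ("greater than" read strictly, "between"
read inclusively; both configurable). "Length" is the alignment-length
column of the hit table. Self hits and within-genome hits are dropped.
Mobile genetic elements are flagged by case-insensitive substring match of
ten keywords (transposase, transposon, conjugative, integrase, integron,
recombinase, conjugal, mobilization, recombination, plasmid) against
product descriptions — substring rather than token matching so that
"transposase-like" is caught.

## The simulator

`simulate_corpus` emulates the statistical structure the measure consumes:
groups of genomes descend from a per-group ancestor gene order; each
descendant independently retains each ancestor gene with probability
`ortholog_retention` (so shared-ortholog counts between two genomes are
Binomial(genes, retention²) — verified by a goodness-of-fit test); gene
order then diverges by circular rotations, block transpositions and
segment reversals — the standard bacterial rearrangement moves, chosen to
exercise both the rotation invariance and the transposition/reversal
sensitivity of the measure; sequences diverge by i.i.d. per-site
substitution with no indels, enough to drive sketch distances. Between-group
pairs share no orthologs, mirroring the observation that synteny signal
concentrates within related groups. Reported ortholog identities are the
realized percent identities of the mutated copies.

Defaults (3 groups × 10 genomes, 30 genes of 900 bp, retention 0.9,
1 rotation + 2 transpositions + 1 reversal, 2 % substitution) describe an
easy, clearly structured corpus: recovery of the true groups at the true
cutoff is the expected outcome, and the test suite requires it in ≥ 90 % of
seeds. What passing these tests shows is that the measure and pipeline
behave correctly under the generative assumptions; real corpora add gene
duplication, horizontal transfer, indels, annotation noise and contig
fragmentation, none of which the simulator models — conclusions about real
data quality must come from real data.

## Problem sizes and limitations

The bundled analyses run at desk scale: corpora of ~30 genomes with ~30
genes each, sketches of 200–1000 hashes, oracle comparisons on genomes of
≤ 6 genes and graphs of ≤ 20 nodes — sizes at which every quantity has an
independently computable reference. The measure itself is O(pairs ×
orthologs³) per genome pair in the worst case (n + 1 arrangements × C(n, 2)
cosines, vectorized), comfortably fast for hundreds of genomes with tens of
shared orthologs. Known limitations: no inversion-aware distance (a single
large reversal and many small ones can score similarly), no nucleotide-level
block discovery (orthologs are taken as given), augmentation assumes both
matrices share exactly the same genome set, and DeltaCon's ε default
follows the max-degree heuristic rather than per-graph tuning.
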