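# Methods

This note documents the models and procedures implemented in `endohgt`, the
defaults chosen where the method leaves a choice open, and the limits of
what the synthetic benchmark demonstrates.

## Genome statistics

GC content is 100·(G+C)/(A+C+G+T); ambiguous bases (`N`, e.g. an unclosed
assembly gap) are excluded from both numerator and denominator so a padded
gap cannot bias the value. GC skew is (G−C)/(G+C) per window, with 0/0
mapped to 0; the default window is 887 bp and the default step equals the
window (non-overlapping tiling), a trailing partial window is included and
flagged. Coding density is the fraction of the replicon covered by the
*union* of CDS intervals — overlapping genes count once. Mean CDS length is
rounded to the nearest integer and percentages are reported to one decimal,
the precision used in genome-table reporting. The rRNA statistic counts
gene *sets* (one per 16S gene; if products are unlabelled, one set per three
rRNA genes), matching how unlinked rRNA operons are tabulated for symbiont
genomes. The transposase census is a lower-cased product-text keyword match
(`transposase`, `insertion sequence`, `is element` by default) against the
deposited annotation — it is an annotation census, not a homology search.

## Pairwise homology and the two screens

Alignments are exact dynamic programming (Biopython `PairwiseAligner`) under
BLOSUM62 with affine gaps costing 11 + k·1 for a gap of length k — the
classic blastp scoring — in local mode for screens. Percent identity is
identities over alignment *columns* (gaps included in the denominator).
E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with the gapped
BLOSUM62-11-1 parameters (λ = 0.267, K = 0.041) and n = total residues of
the searched proteome, so cutoffs are reproducible without a BLAST
installation.

The shared-protein screen calls a query shared when its best-scoring subject
satisfies identity ≥ 25 % and length ratio (shorter/longer — the symmetric
reading of "similarity in size") ≥ 0.8, both inclusive, *and* the best hit
is significant (E ≤ 1e−5 by default). The significance gate reflects that a
database search only surfaces significant alignments: with exact
Smith–Waterman and no gate, roughly a quarter of unrelated random protein
pairs exceed 25 % identity over short local alignments and would be falsely
called shared. One-way best hits define shared-ness; reciprocal best hits
are also flagged in the report so either reading can be tallied.

The AFP screen retains genes whose best alignment against the reference
prophage-protein set reaches E ≤ 1e−10, then groups retained genes into
regions: two consecutive retained genes share a region when at most
`max_gap` (default 5) non-retained genes lie between them. The gap default
is a package choice (the region count is what the analysis reports, the
grouping rule is not standardised) and is recorded in the stage output.
Iterated profile searches (psi-blast-style) are not implemented; homologs
detectable only by profile methods must be supplied via the reference set.

## Synteny

A synton is a maximal chain of ortholog pairs, sorted by gene order in
genome A, where consecutive members advance by 1..max_gap+1 positions on the
A axis and by the same bound on the B axis, monotonically increasing
(conserved) or decreasing (inverted). Chains are assigned greedily, longest
first (ties: smallest starting index, conserved before inverted, then
lexicographically earliest index sequence), each pair belonging to at most
one synton; chains shorter than `min_genes` (default 3, inclusive) are
discarded. `max_gap` defaults to 3 intervening genes per axis; both
parameters are recorded in the output. Greedy rather than globally optimal
chaining is deliberate: it is deterministic, transparent, and adequate at
genome scale.

## Distances, neighbor joining, bootstrap

The default distance is the uncorrected p-distance (share of differing
comparable columns) with pairwise deletion of gapped columns; complete
deletion and the Poisson correction −ln(1−p) are available. The tree method
the donor inference runs on never being stated more precisely than
"neighbor joining", the implementation is canonical Saitou–Nei: join the
pair minimising Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k); branch lengths
by the standard formulas with negative values clamped to zero and the
deficit moved to the sister branch; output unrooted (trifurcating root).
Ties in Q are resolved on the lexicographically smallest leaf labels of the
joined clusters, making trees platform-independent. On additive matrices
the implementation provably recovers the generating tree (property-tested
up to 7 taxa, and cross-checked against scikit-bio's independent NJ).

Bootstrap replicates resample alignment columns with replacement (same
length), recompute distances and the NJ tree; the whole procedure is driven
by one explicit seed. Path metrics treat every tree as unrooted (degree-2
vertices suppressed): the internal-node count is the number of internal
vertices strictly between two leaves — multifurcation vertices count once,
and the count for any two distinct leaves on a ≥3-leaf tree is ≥ 1.

## HGT inference

The candidate rule requires all k = 10 best non-self hits to come from
outside the focal phylum. Genes with fewer than 10 usable hits are
conservatively *not* candidates (reason `too_few_hits`); a lenient mode
accepts all-available-hits-outside instead. Self-hits (subject taxon equal
to the focal organism) are removed before ranking; sharing with the sister
genome is handled by the explicit exclusion rule, alongside product-keyword
exclusions for transposases, repeat proteins and Na⁺/proline symporters
(keyword lists configurable and logged). Subject taxa missing from the
taxonomy table raise an error by default (optionally: treated as
outside-phylum with a warning).

The nearest neighbor is a leaf-level notion — the leaf with the fewest
internal nodes between itself and the query, ties broken by the minimum
branch-length sum, remaining ties by taxon name (logged as a package
convention). Bootstrap support is the percentage of replicate trees whose
inferred nearest-neighbor *category* matches the reference category:
category-level (rather than exact-taxon) agreement is the level at which
donor profiles are reported, and it is robust to within-category leaf
swapping; exact-taxon identity is still available from the per-replicate
calls. Retention requires support strictly greater than 75 % *and* the same
neighbor category in the neighbor-joining and maximum-likelihood trees.
ML trees are ingested as Newick (re-implementing ML inference is out of
proportion to its role as a consistency cross-check); when none are
supplied, the pipeline builds the second tree from Poisson-corrected
distances, so the consistency filter still compares two differently
modelled trees. When the two trees contain different leaf sets, consistency
is evaluated on each tree's own nearest-neighbor category.

Category summaries report counts and percentages per category (AM, AA, ART,
E, X) over both denominators — retained calls and all candidate calls —
because either convention is defensible.

## Synthetic data: what it emulates, and what it does not

The generator emulates a reduced arthropod-symbiont genome against a larger
sister genome: ancestor proteins uniform over the 20 amino acids (lengths
100–400 aa), sister orthologs derived by i.i.d. per-site substitution to
one of the 19 other residues — so expected ortholog identity is exactly
100·(1−divergence), enabling closed-form distributional tests — plus
planted collinear blocks in otherwise shuffled gene order, and planted HGT
genes with donor taxa of known category. Defaults define the benchmark
conditions: 300 genes, 30 HGT events, sister divergence 0.2 (≈ 80 %
ortholog identity, comfortably above the 25 % screen threshold), HGT gene
to donor divergence 0.05, 12 taxa per gene tree, 200 bootstrap replicates,
sister-ortholog fraction 0.67 (mirroring the two-thirds proteome overlap
typical of such genome pairs), donor-category mix ART 0.38 / AA 0.24 /
AM 0.14 / X 0.16 / E 0.08 (the ecological profile reported for
arthropod-symbiont HGT partners), and nucleotide background GC 0.36.
Hit tables are constructed to be consistent with the planted history: HGT
genes have their ten best hits from outside-phylum donor-lineage taxa with
identities decreasing in rank, vertical genes always carry a within-phylum
hit at rank 1; E-values are a deterministic monotone function of bit score
(internally consistent, not physically calibrated). One seeded NumPy
generator drives each call; identical configurations produce byte-identical
datasets.

Passing the recovery benchmark (recall ≥ 90 % of planted events,
false-positive rate ≤ 5 % among vertical genes, ≥ 80 % of retained calls
with the planted category) shows the chain is *correct and well-calibrated
under its own assumptions*. It does not show robustness to what real data
add: alignment errors and indels (simulated alignments are gap-free; gap
handling is exercised by hand-built fixtures), rate heterogeneity and
long-branch effects, database taxon-sampling bias, paralogy confounded with
transfer, or contamination. The published candidate lists and donor
fractions also depend on the contemporary contents of the searched
database, which is why they are benchmarked by simulation rather than
recomputed.

## Numerical and degenerate-input conventions

Windows with G+C = 0 report skew 0. Distance pairs with no comparable
columns are errors naming the pair, as is a Poisson correction at p = 1.
Negative NJ branch lengths are clamped to zero (deficit to the sister edge)
so path-length sums stay non-negative for the tie-break. Newick round trips
preserve topology, lengths to six decimals, and supports (numeric internal
labels in [0, 100]); unbalanced parentheses are reported with a character
offset. Hit-table ranks, when absent, are assigned by descending bit score
with ties broken by ascending E-value then subject id; supplied ranks must
be 1..n with non-increasing bit scores. Coordinates are 1-based inclusive
at every file boundary (the GenBank convention); interval arithmetic is
0-based half-open internally. Compound GenBank locations (joins) are
rejected with a clear error rather than silently approximated.

## Problem sizes used in checks

The oracle property suite runs on small randomised instances (trees up to
40 leaves, additive matrices up to 7 taxa, 50-pair synteny instances,
30-mer alignment pairs, exhaustive screen compositions up to 12 hits); the
recovery benchmark runs the full default conditions above. The acceptance
script executes the complete file-based pipeline on the default synthetic
dataset with 200 bootstrap replicates; the bootstrap default for real
analyses remains 2000.
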