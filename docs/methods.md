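# Methods

This note documents the models and procedures implemented in `pannlrome`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Domain classification

Domain tables carry one interval per predicted domain in 1-based protein
residue coordinates with a source tag (`pfam`, or one of the three
coiled-coil tracks `coils` / `paircoil` / `nlrparser`). Pfam accessions are
canonicalized before any logic runs: PF00931→NB, PF01582→TIR, PF05659→RPW8,
and the four LRR family models (PF00560, PF07725, PF13306, PF13855) all map
to a single LRR token.

Coiled-coil consensus is residue-wise: a residue counts as CC when covered
by intervals from at least two distinct predictor tracks
(`cc_vote_min = 2`); accepted residues are merged into maximal intervals.
This makes the consensus monotone — adding predictor intervals can only
grow it — which is the property the tests enforce.

NLR identification requires at least one of {NB, TIR, RPW8}; LRR or CC
signals alone never qualify. Class assignment uses the precedence
TIR → TNL, RPW8 → RNL, CC+NB → CNL, NB → NL. The four textual class rules
overlap (a gene can carry both TIR and CC); the precedence order turns them
into a partition, following the naming convention in which the TNL/RNL
N-terminal domains dominate. Architectures are collapsed domain sets —
duplicate- and order-independent — so `TIR–NB–LRR–LRR` and `LRR–NB–TIR`
share one architecture key; the ordered domain list is retained as metadata
only. Integrated domains (any non-canonical label inside an NLR) seen in
exactly one gene model of exactly one accession are flagged singletons and
excluded from novelty counts, limiting the effect of annotation artifacts.

## Orthogroup clustering

Similarity edges come from exact local alignment (Smith–Waterman through
Biopython's C aligner) with BLOSUM62 and affine gaps; in this package's gap
convention the first gap residue costs 11 and each further residue 1.
Scores below a floor of 50 are dropped (a lenient homology cutoff);
normalized scores divide by the smaller self-score, so identical sequences
score 1.0. A deterministic shared-4-mer prefilter (≥3 shared 4-mers,
computed for all pairs at once via a sparse gene×k-mer product) skips pairs
that cannot reach the floor; at the package's working identity regimes
(within-family ≥80%, between-family ≤40%) this does not change the edge
set, only the runtime.

Edge typing follows the orthAgogue conventions. For a within-accession pair,
the edge is an inparalog edge iff its score is at least both members' best
between-accession scores. A between-accession edge is an ortholog edge iff
it is reciprocally (co-)best between the two accessions — equal best scores
are kept as co-best, since the original tool's tie-breaking is not
documented. Inparalogs of reciprocal-best partners connect as co-orthologs
where a similarity edge exists. Untyped edges are discarded before
clustering.

Markov clustering runs on the typed, normalized scores at inflation 1.5
with self-loops set to each node's maximum incident weight (standard MCL
practice), pruning threshold 1e-5, convergence tolerance 1e-6 and at most
100 iterations; these last three are determinism/speed choices, as MCL
implementations vary. Clusters are the connected components of the
converged matrix's non-zero structure; clusters with ≥2 genes become OGs
(ids stable: sorted by decreasing size, then lexically), the rest are
singletons. OGs plus singletons always partition the gene universe.

## Refinement

OGs with more than four members are screened and refined; smaller OGs pass
through unchanged (their alignments are still computed for statistics).

*Alignment.* Progressive alignment: 3-mer distances → UPGMA guide tree →
profile–profile global Needleman–Wunsch with BLOSUM62 and the same gap
convention as above. Profiles are residue-frequency columns with gaps
carrying zero weight. Row order is preserved and rows always contain their
input residues. Codon back-translation expands each residue to its codon
("---" for gaps), drops a trailing stop codon, and fails loudly — naming
the gene and the first mismatched residue — if a CDS does not translate to
its protein row.

*Outliers.* Each row's mean pairwise p-distance is bootstrapped over column
resamples; rows whose mean distance z-score against the across-row 10%
trimmed mean exceeds 3 are removed and logged. Fewer than five rows: no
screening.

*Trees.* Neighbor joining (scikit-bio) on nucleotide p-distances with
pairwise deletion of gapped positions; negative NJ branch lengths clamp to
0. Support values come from codon-column bootstrap replicates (default
100), recorded on internal edges as percentages. The distance model is a
deliberate simplification — this package does not do maximum-likelihood or
Bayesian inference.

*Paralogs and the 5% rule.* On the midpoint-rooted tree, an internal node
is a duplication when some accession occurs in more than one child clade;
it is *simple* when the two occurrences are sister leaves, *complex*
otherwise. Let f be the fraction of occupied accessions with within-OG
duplicates (any duplication kind counts). If f ≤ 0.05, all but one copy per
duplicated accession are pruned; the survivor is the copy with the shortest
root-to-leaf path, i.e. the most conserved one — a tie-break this package
defines, since "remove all paralogs" does not name the survivor. Otherwise
the tree is split at duplication nodes (each duplication node is removed,
disconnecting its child subtrees); resulting leaf sets with ≥2 members
become new OGs, the rest singletons. Pruned, outlier and singleton genes
are logged with an explicit status, never dropped silently.

*Annotation.* OG types by size: <13 cloud, 13–51 shell, >51 core. Class and
clustered/paired flags are majority votes over members (class ties resolve
lexically with a warning); the ID flag is set if **any** member carries an
integrated domain. Mean branch length is the tree's branch-length sum
divided by OG size. Physical clusters chain same-contig genes by single
linkage with a 200-kb start-to-start window (so a chain at 0 / 150 kb /
300 kb is one cluster); head-to-head pairs are adjacent same-contig genes,
left on the minus and right on the plus strand, with 5′-end separation at
most 10 kb — the 10-kb bound is this package's choice of a permissive but
bounded limit, given that functionally characterized control pairs sit
within 4 kb.

## Diversity and neutrality statistics

All statistics operate on codon alignments. By default columns with any gap
are removed first (complete deletion); pairwise deletion is available via
the `deletion` switch for the distance-based quantities, and the default is
documented because the reference tooling's behavior is not stated.

With n rows and L retained sites: π = mean pairwise differences / L;
θ_W = S / (a₁·L), a₁ = Σ_{i<n} 1/i; haplotype diversity
H = n(1−Σp_i²)/(n−1); Tajima's D, and Fu & Li's D\* and F\* in the
star (no-outgroup) form with the Simonsen–Churchill–Aquadro corrected
variance constants — no outgroup exists within an orthogroup, so the
starred variants are the only applicable ones. R2 =
√(Σ_i(U_i − π_c/2)²/n)/S with U_i the singletons carried by sequence i and
π_c the mean pairwise difference count. Strobeck's S is the Ewens-formula
probability of at most the observed number of haplotypes given the
per-locus Watterson estimate, computed by the unsigned-Stirling-number
recursion; it is 1 when θ̂ = 0. Statistics that are undefined (S = 0 where
division by S occurs, n below a formula's minimum) are NaN — an explicit
sentinel, never 0.

Per-domain statistics annotate each codon column with the domain claimed by
a strict majority of its non-gap residues (ties and no-majority → `none`;
within one gene, the covering interval with the most C-terminal start
wins), then run the same machinery on the concatenated columns of one
domain. Invariable codons are columns where all rows share one gap-free
3-mer. Flag enrichment is an upper-tail hypergeometric test per (OG, flag)
with Benjamini–Hochberg correction across tests; q < 0.1 is reported.
Expression thresholds subtract a kernel-density estimate of
intron-background counts from the NLR-count density on a shared
log10(count+1) grid and return the lowest level with positive difference.

## Saturation

OG discovery rarefaction draws accession subsets of each size from 2 to the
panel size **without replacement** (the question is what k accessions
reveal; a with-replacement bootstrap would misstate it), 1000 replicates by
default, and reports the mean discovered fraction, 2.5/97.5 percentile
bounds, and the mean membership size of undiscovered OGs. Diversity
rarefaction (100 replicates by default) recomputes mean π and mean
haplotype diversity over OGs with ≥2 sampled members and divides by the
full-panel values. The saturation point is the smallest size whose mean
discovery fraction reaches the target (default 95%).

## Anchoring

The co-occurrence graph has one node per OG and an edge weighted by the
number of accessions in which both OGs occur on the same contig — counted
once per accession even when an accession contributes several such contigs,
because the support threshold is phrased in accessions and per-contig
counting would inflate it. Edges below 10 supporting accessions are
dropped; connected components with ≥2 nodes are subnetworks. A
non-reference OG in a component with anchored nodes receives the reference
interval of its highest-weight anchored neighbor (ties → smallest genomic
coordinate) — an automated, documented proxy for what would otherwise be
manual inspection of assemblies.

## Assembly quality

Q = |−10·log₁₀(hetsites/totalsites)|; the absolute value is retained from
the score's definition although the ratio never exceeds 1. Zero
pseudo-heterozygous sites yields an infinite ("perfect") Q. Completeness
estimates interpolate a monotone (quality, completeness) calibration table
piecewise-linearly, clamped at the table's ends; producing the calibration
table itself (subsampled reference reads → assemblies) requires an external
assembler and is out of scope — the table is an input. IBS is the fraction
of pairwise-complete biallelic sites with identical calls.

## The synthetic pan-NLRome generator

The generator is first-class, tested code, and its defaults define the
package's study conditions: 64 accessions and a 150-OG presence spectrum —
34 OGs at presence probability 0.95, 46 at 0.5, 70 at 0.12 — chosen to
mirror the roughly 23% / 31% / 46% core:shell:cloud proportions of real
species-wide NLR panels at a desk-scale OG count. Per-OG member sequences
descend from a random ancestral open reading frame (150 codons) along a
Kingman coalescent genealogy (exponential waiting times, time in units of
2N) with Poisson mutations on branches under Jukes–Cantor, at per-site
θ = 0.02 — high for a single species but convenient for exercising the
statistics, while keeping within-OG protein identity ≳95% and between-OG
identity at random-sequence levels (≤40%), the regime the clustering tests
assume. Mutations that would create an in-frame stop are redrawn (a crude
stand-in for purifying selection against truncations) so CDS/protein pairs
always translate; the neutral-alignment simulator used for statistics
calibration omits this filter. For n = 2 the expected pairwise diversity
per site equals θ, which the tests verify against both the analytic value
and an independent msprime run.

Gene conversion is applied at 0.05 events per gene with exponentially
distributed tract lengths (mean 120 bp) between family members. 5% of OGs
are seeded with a within-accession paralog diverged by an additional 2×θ,
enabling the 5% rule to be tested against known truth. About 5% of genes
carry an integrated domain drawn from a fixed catalogue of 10 labels
(labels arbitrary — their distribution is what matters). 10% of OGs are
arranged as divergently transcribed head-to-head pairs (1–4 kb apart);
roughly 40% of the remaining OGs are grouped on shared contigs (2–4 OGs per
group, intergenic spacing uniform in 2–50 kb), one contig per physical
cluster plus singleton contigs, mimicking the fragmentation of
capture-based assemblies. Genes receive rare random curation flags
(`truncated` 2%, `pseudogene` 1%). Truth tables record each gene's OG,
architecture, pairing and cluster membership; output is deterministic given
the seed, byte-identical across runs.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: read-level and assembly error, annotation error
beyond the random flags, unequal gene lengths and domain-architecture
variation within an OG, recombination between OGs, population structure
among accessions, and any birth/death model of NLR family evolution (the
presence spectrum is user-set, not evolved). Truth-recovery results
therefore demonstrate correctness of the inference machinery under clean
separations, not expected accuracy on noisy assemblies.

## Problem sizes and determinism

Every stochastic step takes an explicit seed (numpy Generator); pipelines
are idempotent given config + seed. The shipped validation runs use the
default 64-accession / 150-OG panel for truth recovery, 250–400 replicates
for the coalescent calibrations, 1000 replicates for the diagonal-matrix
rarefaction check, and 20 seeded runs for anchoring reliability; tree
bootstrap is disabled in the batch runs and exercised separately on small
alignments. These sizes are the package's validation conditions; the
machinery itself has no hard limits beyond memory.
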