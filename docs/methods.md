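# Methods

## Scope and model

`phylopbs` treats a phylogenomic analysis as a chain of well-defined
transformations: gene families with guide trees → ortholog sets →
partitioned supermatrix → most-parsimonious tree(s) → per-(node, partition)
support → per-node functional enrichment. Everything downstream of the
alignments is parsimony-based and topology-only: no branch lengths are
estimated, characters are unordered multistate symbols scored by Fitch's
algorithm, and a "node" is always a nontrivial bipartition of the unrooted
taxon set (rooted inputs are unrooted before support is computed, because
Bremer-type support is a branch attribute).

## Orthology

ESTs join a family when their best hit reaches the E-value cutoff
(default 1e-20); ties between families resolve to the lexicographically
smaller family id and are logged. Insertion order is fixed once, up front,
by ascending best E-value (ties lexicographic); each EST attaches to the
branch minimizing the Fitch length of the augmented tree, with ties broken
by the first minimal branch in preorder. Existing leaves are never
rearranged, so placement is O(branches × columns) per EST and
deterministic.

Ortholog sets are extracted from the rooted gene-family tree in postorder.
Maximal single-species clades are first collapsed into composite
(co-ortholog) leaves so that in-paralog pairs travel together. Sibling
lineages merge while their species sets are disjoint; at an overlap (a
duplication) the lineage with fewer distinct species — ties: fewer genes,
then the lexicographically greater gene list — is emitted and the other
continues upward, making the surviving set as large as possible. The
simpler emit-both variant is available (`emit_both=True`) for sensitivity
analysis. Multifurcations are handled by folding children in order of
their smallest gene id. Gene trees built de novo (families without a
usable guide tree) are rooted at the topological center of the longest
path, a documented heuristic.

Co-ortholog sampling keeps one uniformly random gene per species,
deterministic given its seed; the pipeline derives one seed per ortholog
set from the master seed.

## Parsimony engine

Columns are encoded as per-taxon state bitmasks (`?`, and `-` by default,
are fully ambiguous; a flag scores gaps as an extra state), duplicate
column patterns are collapsed into weights, and the Fitch pass runs
vectorized across all columns. On the compact nested-tuple encoding of
unrooted binary topologies, stepwise insertion enumerates each topology
exactly once, so searches on ≤ 9 taxa (configurable) are exhaustive and
provably optimal. Above the cap the search uses random-addition starting
trees refined by NNI or SPR hill-climbing, optionally with a parsimony
ratchet (reweight a random fraction of columns, climb, restore, climb).
Equally parsimonious trees are retained up to a cap (default 1,000) and
canonicalized lexicographically, so all outputs are reproducible given the
seed. Heuristic tie collection is inherently incomplete (local optima
across replicates plus the equal-score ring of the final optimum).

Constrained searches either filter the enumeration (small n) or climb with
a membership filter; `require` starts from the best tree or from a
construction that keeps the constrained side intact as a clade, `forbid`
starts by nudging the best tree across the constrained branch with an NNI.

## Bremer and Partitioned Bremer Support

For each nontrivial bipartition *b* of the best tree, the engine finds the
shortest trees lacking *b* (anti-constraint) and containing *b*; Bremer
support is the score difference, and PBS(b, p) is the partition-*p* length
difference between the two constrained optima. With ≤ 9 taxa a single
per-partition length table over all topologies answers every node exactly;
above that, per-node constrained searches are heuristic and each node is
flagged `exact=False` in the output.

Tied constrained optima make the PBS decomposition non-unique. Three tie
strategies are provided:

* `single` (default) — read partition lengths off one deterministic,
  lexicographically canonical optimum per constrained search. PBS stays
  integral and Σ_p PBS(b, p) = Bremer(b) holds *exactly, always*.
* `min` — minimum partition length across tied optima (the literal
  classical definition). Under ties the per-partition minima may be
  attained on different trees, so the sum identity can fail; this is a
  property of the definition, not of the implementation.
* `average` — mean across tied optima (TreeRot-style); the identity holds
  exactly by linearity but values may be fractional.

`single` is the default precisely because the sum identity is the
established sanity check for PBS tables and integral values are what the
downstream positivity threshold expects.

Bootstrap support resamples whole columns with replacement (multinomial
weights) across partition boundaries; each pseudoreplicate contributes the
strict consensus of its tied shortest trees. Percentages are attached to
the reference tree's bipartitions.

## Supermatrix filters

Representation is the exact rational fraction of matrix taxa with at least
one non-missing character in the partition; thresholds are inclusive ("at
least 30%" keeps a partition at exactly 0.30), and a small floating-point
guard protects the boundary. Genus collapse picks, per partition, the
congener fewest edges below the root of the smallest clade containing the
genus on the reference tree (ties: more non-missing characters in that
partition, then lexicographic), falling back down that ranking when the
chosen species lacks the gene. Because the reference tree is itself the
product of the search stage, genus collapse is exposed as a library
operation rather than wired into the default pipeline order.

## Enrichment

The background population is the union, over nodes, of annotated
partitions with strictly positive PBS (PBS = 0 is excluded). Each (node,
term) pair with at least one study-set occurrence gets the exact
hypergeometric upper tail P(X ≥ k); correction (default
Benjamini–Hochberg, also Bonferroni or none) is applied jointly across all
pairs. Tier counts use strict inequalities (p < 0.01/0.05/0.10) on raw
p-values by default, with adjusted-p tiers reported alongside. An optional
term-hierarchy propagation (child → ancestors before counting) is off by
default.

## Synthetic data: what it emulates and what it does not

The generator's defaults describe a desk-scale analogue of a large
EST-based phylogenomic study: 10 species in 5 genera (one designated
"genome" species per genus founds the guide trees), 200 gene families of
60 aligned residues, duplication/loss rates of 0.4/0.2 per unit branch
length, per-branch lengths uniform on 0.04–0.12 expected substitutions per
site, 20% EST missingness, and annotations with a planted term carried by
half of the target-congruent families against 20 background terms at 10%
frequency.

Two generator design choices matter for interpreting the tests:

* **EST missingness acts at the family level**: a non-genome gene is
  simply never sequenced with probability `est_missingness`, so absent
  species never enter a family. The matrix-level blanking operation
  (`sim_est_sampling`) exists and is tested, but the pipeline's
  missingness is biological, not post-hoc.
* **The target clade sits on a deliberately short stem** (scale 0.1–0.2 of
  its drawn length, default 0.2), emulating a rapid radiation. Support for
  the target node then traces to realized substitutions on one branch, and
  the simulator's congruence flag is ground truth it can actually verify:
  a family supports the target when every clade species is sampled, at
  least two outside species are sampled, the sampled clade genes are
  monophyletic in the true gene tree, and the subtending branch
  accumulated at least `target_stem_min_subs` (default 2) realized
  substitutions. For a root-adjacent clade the unrooted branch is the
  fusion of both root edges and substitutions on either side count.

Sequences evolve under an equal-exchange-rate model with a uniform root
and Poisson substitution counts per site and branch; there are no indels
(parsimony treats gaps as missing, so indels add no test power), no rate
heterogeneity across sites, no codon structure, and no transfer events.
Hit-table E-values are a monotone transform of pairwise identity
(10^(−150·identity), floored), not a BLAST statistic. Passing tests on
these data therefore demonstrate the correctness and calibration of the
*machinery* — extraction rules, search optimality, the PBS identity,
exact tail probabilities, type-I error, planted-signal recovery — not the
robustness of the method to alignment error, heterotachy, or the taxon
densities of real EST corpora.

Every quantity is driven by one master seed; two runs with the same
configuration produce byte-identical output files, and the event log
(duplications and losses with the species count of their branch) is
sufficient to compute ground-truth ortholog group counts independently of
the orthology module: with no losses, each duplication on a branch
spanning ≥ 2 species adds exactly one set, while within-species
duplications only create co-ortholog groups.

## Statistical calibration experiments

The type-I check assigns terms independently of the positive-PBS profile
(500 families, 25 terms at 40% frequency, positives drawn at rate 0.5 per
node) and requires the fraction of raw p < 0.05 over 2,000 (node, term)
tests to sit within three binomial standard errors of 0.05. The
hypergeometric tail is discrete, so this fraction is structurally slightly
below 0.05; the experiment's size was chosen so that the discreteness
shortfall is small compared to the tolerance band, which is exactly what a
calibrated-but-discrete exact test should show. The power check (planted
0.5 vs background 0.1, 200 partitions, 50 replicates) uses the event-level
simulator only, with duplication/loss-free families as the
target-congruent class.

## Problem sizes

Exhaustive analyses run at 5–8 taxa (up to 10,395 topologies); the
end-to-end pipeline runs at the 10-taxon / 200-family default, where tree
search and per-node constrained searches are heuristic (flagged as such in
the outputs). These sizes keep every acceptance computation within a few
minutes on a single core while still exercising each code path, including
the heuristic ones.

## Known limitations

* Heuristic PBS values at > 9 taxa depend on search effort; underestimated
  anti-constraint optima inflate PBS. The run log flags exact vs heuristic
  nodes.
* The `min` tie strategy cannot guarantee the PBS-sum identity (see
  above); it is provided for comparability with the literal definition.
* Bootstrap resampling ignores partition boundaries (standard character
  bootstrap); per-partition resampling is not implemented.
* The EST placement score is exact for the fixed-tree insertion it
  performs, but early placement errors can cascade (insertions are never
  revisited), as in the stepwise protocol it models.
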