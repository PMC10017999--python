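# Methods

## Identification and classification

A gene is an NLR candidate when its protein carries at least one NB-ARC
domain hit with E-value ≤ `nlr.e_threshold` (default 1e-4, the conventional
hmmer cutoff for this family). An optional second pass walks a homology
table: any gene hitting a confirmed NLR at E ≤ 1.0 is re-checked for a
significant NB-ARC hit and dropped otherwise, so the candidate set never
relaxes the NB-ARC requirement.

The architecture string is built per gene: same-domain hits overlapping by
≥ 1 aa are merged (ties on start go to the longer hit), hits are ordered by
alignment start, and consecutive identical letters collapse, so two LRR
hits yield a single `L`. Domains outside {CC, TIR, RPW8, NB-ARC, LRR} are
ignored. Subclass priority is RPW8 > TIR > CC/none: RPW8 anywhere → RNL,
else TIR → TNL, else CNL. A coiled-coil hit is never *required* for CNL
membership — CC domains are systematically under-called by profile scans,
and requiring them would misclassify most incomplete CNLs.

Motif presence (P-loop `G..GKT[TS]`, Kinase-2 `[LIVM][LIVM]DD`, RNBS-B
`[GS]R..[LIVM]`, GLPL `GLPL`) is a deterministic left-to-right regex scan
inside the best NB-ARC region. Published motif evidence is a sequence logo,
not a string, so the patterns are configuration, not constants.

## Locus clustering

Distance between two NLRs is the inter-gene gap (`next.start − prev.end − 1`,
floored at 0 for overlapping genes), not start-to-start: the window rule
describes a region *flanking* a gene, which references gene boundaries.
Chaining is transitive (single linkage) with a strict `< window` test
(default 250,000 bp), so a run of genes each within the window of its
neighbour is one cluster — the behaviour a sliding window produces. Genes
on unplaced scaffolds are reported as unmapped and excluded from both
chaining and percentage denominators. Cluster ids are assigned by leftmost
start per (species, chromosome), making output order-independent.

## Duplication typing

Gene ranks are 0-based positions among **all** genes (not only NLRs) on a
chromosome, ordered by start (ties: end, then id). Collinear blocks are
greedy longest chains over homology dots in rank space, per chromosome
pair, in both orientations, with per-step rank gaps ≤ `dup.max_gap_ranks`
(default 25) on both axes and a minimum of `dup.min_block_pairs` (default
5) pairs — the MCScanX parameterisation. Same-chromosome dots closer than
`max_gap_ranks` ranks are excluded from chaining: they are tandem/proximal
evidence, and large tandem arrays would otherwise self-chain into spurious
"segmental" blocks. Paralogy for typing requires a homology edge with
E ≤ 1e-10 and identity ≥ 30% (configurable). Precedence is
WGD/segmental > tandem > proximal > dispersed > singleton, applied only to
chromosome-mapped NLRs, so the four categories plus singletons always
partition the mapped set.

## NBS phylogeny

The NB-ARC region is the substring of the lowest-E NB-ARC hit (ties:
longer, then earlier); regions shorter than `tree.min_nbs_len` (default
80 aa) are excluded as uninformative. Distances are p-distances with
pairwise gap deletion; sequences must be equal length — synthetic NBS
blocks are indel-free by construction, real data must arrive pre-aligned
(multiple alignment is deliberately out of scope; it is a solved problem
served by external tools).

Neighbor joining uses the Q criterion with Studier–Keppler distance
updates. Determinism is pinned: ties in Q resolve to the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest
member leaf), and negative branch lengths clamp to zero. Rooting options:

* **midpoint** — half-way along the longest leaf-to-leaf path;
* **outgroup** — on the edge separating the given labels, which must form
  one side of an edge of the unrooted tree;
* **duplication-loss parsimony** (used for reconciliation input) — every
  edge is tried as the root and the reconciliation-cheapest one wins, with
  midpoint rooting breaking ties. This mirrors how reconciliation tools
  select a root on unrooted gene trees; on clock-like data the midpoint
  tie-break uses the rate signal parsimony cannot see.

## Reconciliation

LCA mapping is computed bottom-up; an internal node is a duplication iff
its image equals the image of at least one child. Losses on a gene-tree
edge (p, c) number `d(M(p), M(c)) − 1 + e(p)` with `e(p) = 1` for
duplications (0 when the images coincide), each placed on the off-path
child branch of a traversed species node, starting at `M(p)` itself for
duplications. LCA reconciliation simultaneously minimises duplications and
losses; an exhaustive mapping-enumeration oracle (used in tests and to
project simulated truths) confirms minimality on thousands of random
instances.

Ancestral lineages at the species root are the distinct gene copies the
root ancestor must have carried: speciation nodes mapping to the root, plus
children of root-mapped duplications whose own mapping lies strictly below.
Root-mapped duplications therefore enlarge the lineage count and are *not*
branch gains — lineage counts and per-branch ± numbers are disjoint
quantities. A family whose root maps below the species root contributes no
lineage; it is reported as a post-root gain, counting one origination gain
on the branch it maps to, so per-species leaf counts are conserved:
lineage members plus post-root-gain descendants equal the species' gene
count. Per-lineage subclass is the majority subclass of its members (ties
→ "mixed"). Branch patterns: expansion iff gains > losses, contraction iff
losses > gains, else stable.

Input polytomies are resolved deterministically (caterpillar by sorted
leaf label, zero-length edges) with a logged warning. Support-threshold
rearrangement of weak edges is a non-goal: no edge-support evidence enters
the desk-scale pipeline.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuned:

| parameter | default | meaning |
|---|---|---|
| species tree | `(Dc,(Ag,(Cs,As)))`, ultrametric, depth 3 | four-taxon topology with carrot splitting first |
| `dup_rate`, `loss_rate` | 0.2, 0.2 per gene per branch | moderate turnover giving ~3–4 genes/family, matching the few-hundred-genes-over-~180-lineages regime of real NLR repertoires |
| `n_root_genes` | 1 | one ancestral copy per family |
| `nbs_length` | 300 aa | the NB-ARC domain's natural size |
| `sub_prob` | 0.02 per site per unit branch length | clock-like divergence; tip-to-tip p-distances ≤ ~0.12 |
| `tandem_prob` / `proximal_prob` | 0.40 / 0.15 | multi-copy groups planted as tandem arrays / proximal runs |
| `scaffold_frac` | 0.05 | groups placed on unplaced scaffolds to exercise "unmapped" handling |

On each species branch entered by `n0` copies, Poisson(rate × n0)
duplication and loss counts are drawn, event times are uniform over the
branch, and events apply sequentially to a uniformly chosen extant copy (a
branch-start-intensity approximation of the linear birth–death process;
adequate at these rates). Extinct lineages are pruned and unifurcations
suppressed for the observable tree. The **parsimony-projected truth** —
what a parsimony reconciler can at best recover — is computed by running
the brute-force oracle on the true pruned tree, never the reconciler under
test. Raw and projected counts coincide exactly when the loss rate is zero.

Proteins concatenate fixed per-domain prototype blocks (CC 60, TIR 120,
RPW8 80, NB-ARC `nbs_length`, LRR 150 aa); the family root sequence is
perturbed at 25% of sites for between-family divergence, and each pruned
edge substitutes each site with probability `sub_prob × duration` (one
round per edge, so multiple hits within an edge are not modelled). Genomic
placement isolates family groups with filler-gene runs that exceed **both**
the 250-kb cluster window and the block chainer's rank gap, so planted
cluster memberships and duplication types (tandem: adjacent ranks, 5–50 kb
gaps; proximal: 1–8 fillers between copies; dispersed: different
chromosomes or > 250 kb apart; singleton: single copy in the species) are
unambiguous by construction. Emitted E-values are log-uniform in
[1e-60, 1e-10]; homology identity is 100·(1 − observed divergence).

What the simulator does *not* emulate: indels and domain shuffling (NBS
blocks are alignment-free by design), rate variation across sites and
lineages, codon structure, GC bias, realistic genome sizes, and
hybridisation/transfer. Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not robustness to
alignment error or model misspecification on real proteomes.

## Measured performance of the estimation chain

With the defaults above (problem sizes: 200 families of ≤ 8 genes, 2,000
random reconciliation instances, 100 additive matrices), the acceptance
script measures: exact agreement of the LCA reconciler with the exhaustive
oracle (100%), exact NJ topology recovery on additive matrices (100%),
exact per-family event recovery with true gene trees (100%), and ~92–94%
exact per-family event recovery end-to-end with estimated trees. The
end-to-end gap has two irreducible sources at these settings: families
containing an internal edge with fewer than ~3 expected substitutions,
which no distance method can resolve from 300 aa; and families whose true
rooted history is strictly costlier than the cheapest rooting of their own
(correctly estimated) unrooted topology, which no rooting rule can recover.

## Numerical conventions

Printed percentages and ratios use decimal half-up rounding at 2 decimals
(`decimal.Decimal`, never binary-float rounding). Coordinates are 1-based
inclusive throughout (GFF3 and hmmer conventions). Newick output writes
branch lengths at 6 decimals; round-trips preserve topology, labels and
lengths at that precision. Gene-tree leaves are labelled `SPECIES|gene_id`
with `|` reserved. All simulation randomness flows from a single mandatory
integer seed through named substreams, so identical configuration and seed
reproduce byte-identical outputs.
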