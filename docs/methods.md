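# Methods

## The inference problem

An allopolyploid lineage carries two subgenomes contributed by two
diverged parental lineages.  In a standard (singly-labelled) species tree
this history is invisible, but it leaves a genome-wide signature in gene
trees: each family may retain both homeologs (producing two parallel
copies of the polyploid clade) or lose one copy per descendant lineage.
Following the GRAMPA-style approach, we represent each polyploidy
hypothesis as a *MUL tree* — a species tree in which the species of a
candidate polyploid clade H1 appear twice, the original copy tagged `*`
and a grafted copy (attached on the edge above a second node H2) tagged
`+`.  H2 = H1 encodes autopolyploidy (the copy becomes H1's sister);
H2 = root attaches the copy above the present root.  Reconciling every
gene tree against every candidate and summing duplication+loss scores
ranks hypotheses: the reference that minimizes total score best explains
the gene-tree population.

On a binary species tree with node set N the candidate space has size
1 + Σ_{h1 ≠ root} (1 + |N| − |subtree(h1)|); for the 8-taxon tree used
throughout (outgroup + 3-taxon ladder + 4-taxon ladder) this is 181.
Placements are deliberately not deduplicated by topology — the search
space is counted in placements, and several distinct placements
(e.g. H1 = ingroup with H2 ∈ {SELF, ROOT}) can imply similar gene-tree
expectations while differing in tag geometry.

## Reconciliation model

Scoring is classical LCA duplication–loss reconciliation on rooted binary
trees, topology-only (branch lengths are parsed and ignored):

* each gene leaf maps to the reference leaf of its species (and copy
  tag, for MUL references);
* each internal gene node maps to the LCA of its children's images;
* a gene node is a **duplication** iff it maps to the same reference node
  as at least one child;
* **losses** per child edge are `d(M(g), M(c)) − (0 if g is a duplication
  else 1)`, with `d` the reference edge-count from the child's image up to
  the node's image; no losses are charged above the gene-tree root or on
  the reference root edge.  Only score *differences* between candidates
  matter for ranking, so the boundary convention is harmless.

Against a MUL reference, leaves of duplicated species are ambiguous.  We
collapse the gene tree into **polyploid groups**: maximal connected
subtrees whose leaves all belong to duplicated species *and contain at
most one leaf per species*.  Each group is assigned en bloc to one
subgenome copy and all 2^g assignments are enumerated (g ≤ 8 by default;
trees above the cap are excluded and counted).  The one-copy-per-species
condition is essential: a subtree holding two copies of the same species
necessarily straddles both subgenomes, so collapsing it would make the
two-subgenome split of a fully retained family inexpressible and the true
MUL candidate would never beat the singly-labelled tree.  With the
condition, the group search is exact whenever groups are singletons and
otherwise an upper bound on the per-leaf optimum; both facts are enforced
in tests against a per-leaf brute-force oracle (≤ 2^12 assignments) and,
for the singly-labelled case, against an independent quadratic-time
implementation.

Ties are resolved deterministically everywhere: equal-score assignments
prefer more `*` tags, then lexicographic order; equal-score candidates
keep enumeration (preorder) order.

## Scenario classification

Restricted to the focal clade (cladeA = "other"-like, cladeB =
"core"-like), a family that kept or lost whole homeolog copy-clades shows
one of three canonical topologies, matched on the induced subtree's first
two levels (strict mode):

* **T1** `(A, (A, B))` — root children: one A-only, one binary with an
  A-only and a B-only child → the `+` copy was lost in cladeB;
* **T2** `(B, (A, B))` — one copy lost in cladeA;
* **T3** `((A, B), (A, B))` — both copies retained in both clades;
* **U** — anything else, notably reciprocal loss `(A, B)`.

Matching keys on clade *composition*, never on copy tags (tag orientation
is not observable in a gene tree).  Lenient mode relaxes the patterns to
the A-only/B-only/mixed composition of the two root children, which
real multi-copy families need; strict is the default because the
canonical patterns are literal.  Multifurcating induced roots and
sub-2-leaf inductions are labelled U and logged, not errors.

## Gene-tree filters

The preliminary filter removes trees with more than 8 polyploid groups
(bounding the assignment enumeration).  The deep filter bounds gene copy
number per species; the adopted default is **presence required, 1–4
copies inclusive**.  The narrower ("2–3") and wider ("1–5") literal
readings of the copy-number rule are mutually inconsistent in the
source workflow's own description, and [1, 4] is the only reading under
which single-copy families — which carry the strongest T1/T2 signal —
survive.  Both alternatives remain selectable in `FilterConfig`.

## Enrichment

Per scenario, category over-representation uses the exact upper-tail
hypergeometric probability P[X ≥ k] for X ~ HG(N, K, n) (integer-exact
rational arithmetic for N ≤ 2000, stable log-binomials above), followed
by Benjamini–Hochberg adjustment *within* each scenario (the scenarios
are separate panels, hence separate families of tests).  One-sided tests
only: the question is which functions are biased toward a scenario.
Unannotated families stay in the universe N but add to no K
(conservative).  Whether the universe is all families or only classified
ones is a config choice (`all` by default).

## Synthetic data generator

`mulrecon.simulate` emulates the generative process the analysis assumes.
The true history is the MUL tree for a configurable placement (default:
H1 = the whole focal clade, H2 = SELF, i.e. the two subgenomes appear as
sister clades — the standard representation when both parental lineages
are unsampled).  Events, in order, from one seeded `numpy` generator:

1. **Clade-level copy loss** — four Bernoulli draws with probabilities
   `a` (lose `+` in cladeB), `b` (lose `*` in cladeB), `c` (lose `+` in
   cladeA), `d` (lose `*` in cladeA).  These draws *are* the scenario
   structure: with b = c = 0, strict labels follow T1 = a(1−d),
   T2 = d(1−a), T3 = (1−a)(1−d), U = ad.  The truth label is recorded
   here, before noise.
2. **Per-leaf loss noise** `eps` — independent leaf deletions.
3. **Small-scale duplication** `delta` — per-branch subtree duplication.
4. **Topological error** `eta` — probability of one random NNI move.

Defaults (a = 0.4, d = 0.35, b = c = 0, eps = 0.05, delta = eta = 0,
F = 500) are the moderate biased-loss study conditions used by the
analysis scripts and acceptance checks; they were fixed from the scenario
model, not fitted.  Families that end with < 2 leaves, lose their
outgroup leaf, or whose outgroup monophyly is broken by a duplication are
resampled and counted.

Truth records both raw deleted leaves and **parsimony loss events**
(maximal lost MUL subtrees).  With delta = eta = 0 and no reciprocal
whole-copy loss, reconciliation against the true MUL tree recovers the
parsimony count exactly; reciprocal loss (a U family) is intrinsically
explained more cheaply (one loss instead of two) by any minimizing
reconciliation, which is why that identity is stated — and tested — for
regimes with d = 0.

What the generator does **not** model: sequence evolution, alignment
error, incomplete lineage sorting (a real source of gene-tree conflict
with no model here), rate variation, and gene conversion between
homeologs.  Passing tests therefore demonstrate correctness of the
inference machinery under the assumed loss model, not robustness to every
real-data pathology.

## Problem sizes and numerics

The analysis scripts and acceptance checks run 500 families × 181
candidates (≈ 10 s on one core); oracle cross-checks use 200 random MUL
instances (≤ 6 species, ≤ 10 duplicated leaves) and 1,000 random
singly-labelled instances.  All randomness flows from explicit integer
seeds; reruns are byte-identical.  LCA queries walk parent pointers
(trees have ≤ ~30 nodes; no sparse-table machinery is warranted).
Hypergeometric p-values are exact rationals in the regime used here.

## Known limitations

* The per-group assignment is a heuristic upper bound when groups are
  non-singleton (multi-copy families); the brute-force oracle quantifies
  the gap on small instances but large families rely on the heuristic.
* Gene trees are required binary (polytomies can be randomly resolved,
  logged per tree); support values are ignored rather than used for
  collapsing.
* Candidates are scored independently per filtered dataset and combined
  by summation; a tree passing both filters contributes twice to the
  combined table, mirroring the upstream workflow's combined count.
* No DTL (transfer) events, no probabilistic reconciliation, no
  branch-length awareness.
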