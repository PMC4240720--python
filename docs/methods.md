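# Methods

## Model

A gene family `𝒢` evolves inside a species phylogeny by speciation,
duplication and loss.  An evolutionary scenario is abstracted as a *DS-tree*
`(G, ℓ)`: a rooted tree with leaves `𝒢` and every internal node labeled
`Dup` or `Spec`.  Two genes are orthologs w.r.t. `G` when their least common
ancestor is a speciation node, paralogs when it is a duplication node.  A
DS-tree is *consistent* with a species tree `S` when, at every speciation
node, the species-level lcas of any two child subtrees are unrelated in `S`
(neither equal nor ancestrally ordered); equivalently `S` displays every
speciation triplet `s(x)s(y)|s(z)` read off gene triplets `xy|z` rooted at a
speciation with `s(x) ≠ s(y)`.  A *history* is a DS-tree consistent with the
species tree; horizontal transfer is outside the model.

Partial knowledge is a constraint graph `R = (V, E, U)`: orthology edges
`E`, unknown pairs `U`, paralogy as non-edges.  Same-species pairs can never
be orthologs (within a genome, divergence is by duplication), so
same-species orthology edges are rejected at validation and same-species
unknown pairs are normalized to paralogy before any decision.

## Decision procedures

**Satisfiability.**  A full constraint graph admits a DS-tree iff it is
P4-free; a partial one iff some realization `R(F)`, `F ⊆ U`, is P4-free —
the graph sandwich problem for cographs.  `build_ds_tree` implements the
disconnection recursion: leaves for single genes; a `Dup` node over the
connected components of `R(∅)` when it is disconnected; otherwise a `Spec`
node over the co-components of `R(U)` (components of the complement) when
those exist; otherwise the current vertex set is unsatisfiable and is
reported for diagnostics.  The `Dup` split is preferred when both apply,
which fixes the witness deterministically.  Components are ordered by their
lexicographically smallest gene, and unordered pairs are stored smaller gene
first, so identical inputs yield byte-identical witnesses.  Complement
components are found by the unvisited-set BFS trick without materializing
the complement, keeping the whole recursion `O(n³)`.

**Consistency with a given `S`.**  The same recursion, with the `Spec` step
gated by a *speciation partition*: the co-components are grouped by a
preorder traversal of `S`, each part collecting the components whose
species-lca falls inside the subtree of the part's shallowest
representative; a partition with a single part licenses nothing.  This
grouping is canonical — components whose lcas are ancestrally ordered *must*
share a part, so the traversal yields the only candidate partition and no
enumeration of alternatives is needed.  Although a failed `Dup` branch
already implies inconsistency (induced subgraphs inherit consistency), the
implementation still attempts the `Spec` branch afterwards, since the
characterization is a disjunction; the cost is at most a constant factor.

**Consistency with an unknown `S`.**  Orthology-only constraint sets are
satisfied by per-species duplication stars under one speciation root, and
paralogy-only sets by a single duplication star; both are consistent with
the star species tree, so these classes are accepted by construction.  For
a full graph, consistency is equivalent to the existence of a species tree
displaying `P3(R)`, the species triplets of induced paths `x–z–y` (edges
`zx, zy`, non-edge `xy`, `s(x) ≠ s(y)`); `build_species_tree` is the BUILD
(Aho) recursion on the triplet constraint graph, returning a least-resolved
flavor of tree: unconstrained splits stay non-binary and species unmentioned
by any triplet attach as free children.  Triplets whose outgroup species
equals a grouped species are undisplayable and fail immediately.  For
partial graphs, `check_cons` branches on unknown pairs (orthology first),
pruning a branch when BUILD fails on the current `P3` — valid because `P3`
only grows as unknowns get resolved — or when the current partial graph is
already unsatisfiable with the remaining unknowns treated as wildcards.
Branching prefers unknown pairs lying inside an induced P4 of `R(∅)`.  The
search is exact but worst-case exponential in `|U|`; a `max_nodes` budget
aborts with an error rather than a wrong verdict.

**Forced-edge preprocessing.**  Before the search, two sound reductions run
to a fixpoint: (a) for every 4-subset spanning exactly one unknown pair,
both assignments are tested for an induced P4 on those four vertices — an
assignment whose alternative is always a P4 is forced, and both-bad is a
contradiction (by heritability, a permanently-P4 quadruple kills every
realization); (b) an induced path `x–z–y` whose chord `xy` is unknown is
forced to orthology when resolving it to paralogy would create a species
triplet contradicting one already in `P3(R)` on the same three species.
Forced values hold in every consistent realization, so preprocessing never
changes the verdict (asserted against the unpreprocessed search in tests).

## The two consistency predicates

`is_consistent` (speciation-node route) and `is_consistent_by_triplets`
(displayed-triplet route) are both exposed and agree on every DS-tree that
respects trivial paralogy.  The one divergence arises for degenerate trees
in which a speciation node joins two subtrees whose species sets are the
same singleton — i.e. a same-species orthologous pair, which no valid
constraint set or history can contain: the node route rejects them while no
triplet witnesses the violation.  The random DS-tree generator used in the
equivalence tests therefore relabels any speciation node whose child
subtrees share a species as a duplication, sampling exactly the class of
trees the model admits.

## Synthetic data generator

`simulate` emulates what the decision procedures consume in practice,
without modeling sequences, branch lengths or rates:

* **Species tree** — Yule (pure-birth) topology: repeatedly split a
  uniformly chosen extant lineage until `n_species` leaves (default 8,
  a typical small vertebrate panel).
* **History** — one gene lineage enters the root; at every species-tree
  node each lineage speciates into all children; along each branch a
  lineage duplicates with probability `dup_prob` (default 0.2, a
  moderately duplicating family; geometric chain capped at 4 per branch)
  and is lost with probability `loss_prob` (default 0.1).  Losses are
  applied as post-hoc pruning with suppression of unary nodes; event labels
  survive on the remaining nodes, so the pruned history stays consistent
  with the species tree.  Extinct families trigger a bounded retry.
* **Constraint graphs** — the *truth* is the full graph induced by the
  history.  `mask_frac` of the cross-species pairs move to `U` (default
  0.25, mimicking the roughly-half-known graphs that combining two
  predictors produces), then `flip_frac` of the remaining known
  cross-species pairs invert orthology↔paralogy (default 0, used to
  fabricate unsatisfiable/inconsistent instances).  Same-species pairs are
  never masked or flipped — they are hard paralogy.  Masking and flipping
  draw from random substreams separate from the topology stream, so varying
  them never changes the underlying history.

Because masking only relaxes the truth, every uncorrupted derived graph is
satisfiable, consistent with the generating species tree, and consistent
with some species tree; the test suite verifies this closure across seeds
and masking levels.  What passing these tests does *not* show: behavior on
real predictor output whose errors are correlated (e.g. systematic
under-prediction of orthology between distant species) rather than
independent flips, or on families whose size distribution differs from the
birth-process model.

## Numerical and scaling choices

There is no floating-point arithmetic anywhere in the decision path; all
procedures are exact set/graph manipulations, so determinism reduces to the
ordering conventions above.  Oracle-backed tests run the brute-force
enumerations where they are affordable in pure Python: satisfiability is
checked against realization enumeration exhaustively for every bicolouring
on up to 5 genes and on sampled 6–7 gene graphs (unknown sets capped at 12
pairs to bound the 2^|U| oracle); consistency oracles (all realizations ×
all DS-trees on the leaf set, plus all species trees for the unknown-`S`
case) run exhaustively for 3 genes × all species maps × all species trees
and on several hundred sampled 4–5 gene instances over ≤ 4 species; witness
audits cover a thousand simulated instances up to ~30 genes, with the
branch-and-bound audited on the subset small enough (≤ 14 genes, and ≤ 10
when corrupted) to bound its exponential worst case; the polynomial
procedures are additionally exercised on a ~300-gene instance.  These sizes
are the package's own test-design choice: they are the largest instances at
which the *independent* oracles remain exhaustive, which is what makes the
comparisons meaningful.

## Limitations

* `check_cons` is exponential in `|U|` in the worst case (the complexity of
  partial-graph consistency is open); the node budget is the only guard.
* BUILD returns one displaying species tree, not a canonical least-resolved
  one, and no attempt is made to extract maximum consistent subsets when the
  answer is negative.
* Witnesses are the star-join trees the recursions construct; they are not
  binarized and carry no reconciliation costs.
* The relations file format cannot express weighted or directed constraints,
  and unknowns are implicit (any unlisted cross-species pair), so a file
  cannot distinguish "unknown" from "unexamined".
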