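# orthosat

Satisfiability and species-tree consistency of partial orthology/paralogy
constraints on gene families.

## The problem

Orthology detection tools (sequence clustering, synteny, functional
annotation) produce pairwise statements about the genes of a family: *x and
y are orthologs* (they diverged at a speciation) or *x and y are paralogs*
(they diverged at a duplication).  Unlike tree reconciliation, such methods
constrain only *some* pairs.  Before using these constraints — e.g. to
correct a gene tree — one should ask whether they can co-exist in any
evolutionary scenario at all.  `orthosat` answers three questions about a
constraint set `C = (C_O, C_P)` on a gene family `𝒢` with species map
`s : 𝒢 → Σ`:

1. **Satisfiability** — is there an event-labeled gene tree (*DS-tree*
   `(G, ℓ)`, internal nodes labeled `Dup`/`Spec`) inducing every constraint,
   i.e. `ℓ(lca_G(x,y)) = Spec` for `xy ∈ C_O` and `= Dup` for `xy ∈ C_P`?
2. **Consistency with a given species tree `S`** — is there such a `G` whose
   speciation nodes group genes in agreement with `S` (equivalently, `S`
   displays every speciation triplet of `tr_S(G)`)?
3. **Consistency** — is there *some* species tree for which (2) holds?

Constraints are held as an edge-bicoloured graph `R = (V, E, U)`: orthology
edges `E`, unknown pairs `U`, paralogy implicit as non-edges.  Choosing
`F ⊆ U` gives the realization `R(F)`, a full graph.

## Algorithms

* A full graph is satisfiable iff it is **P4-free (a cograph)**; for partial
  graphs this becomes the graph sandwich problem for P4-free graphs, decided
  in `O(n³)` by a disconnection recursion: a vertex set admits a DS-tree iff
  it is a single gene, or `R(∅)` is disconnected (join components under a
  `Dup` node), or the complement of `R(U)` is disconnected (join under
  `Spec`).  The recursion *is* the witness constructor.
* For a fixed species tree the `Spec` step additionally requires a
  **speciation partition**: a grouping of the complement components whose
  species-level lcas are pairwise unrelated in `S`, found by one preorder
  traversal of `S`.
* For an unknown species tree, the mandatory triplet set
  `P3(R) = { s(x)s(y)|s(z) : zx, zy ∈ E, xy a non-edge, s(x) ≠ s(y) }`
  characterizes consistency of full graphs: `R` is consistent iff some tree
  displays `P3(R)`, decided by the **BUILD** (Aho) supertree recursion.
  Partial graphs are handled by a branch-and-bound over `U` that prunes on
  BUILD failure and on unsatisfiability, with optional forced-edge
  preprocessing (unknown pairs whose value is implied by a P4 or by a P3
  triplet conflict).
* Orthology-only and paralogy-only constraint sets are always consistent
  (star constructions).

Every positive answer ships auditable witnesses: a DS-tree, the chosen
realization of `U`, and (for consistency) a species tree.

## Worked example

Three genes — `ga` in species `a`, `gd` in `d`, `ge` in `e` — where `ge` is
orthologous to both others, which are paralogs of each other:

```sh
$ cat species_map.tsv          $ cat relations.tsv
ga  a                          ga  ge  orthologs
gd  d                          gd  ge  orthologs
ge  e                          ga  gd  paralogs

$ orthosat sat --relations relations.tsv --species-map species_map.tsv \
    --witness-out witness.nwk
satisfiable
$ cat witness.nwk
((ga,gd)D,ge)S;
```

The witness places the duplication `ga|gd` below the speciation with `ge`,
so the gene-level triplet `ga gd | ge` is rooted at a speciation: the
species triplet `ad|e` is *forced*.  A species tree with `de|a` therefore
fails, while consistency with an unconstrained species tree succeeds and
returns a tree displaying `ad|e`:

```sh
$ orthosat cons-with-tree --relations relations.tsv \
    --species-map species_map.tsv --species-tree <(echo "(a,(d,e));")
inconsistent
$ orthosat cons --relations relations.tsv --species-map species_map.tsv \
    --species-tree-out inferred.nwk
consistent
$ cat inferred.nwk
((a,d),e);
```

Exit codes: 0 positive verdict, 1 negative, 2 input error, 3 search budget
exceeded.  `orthosat simulate` generates synthetic instances (species tree,
duplication/loss history, true relations, masked/corrupted constraints) for
experimentation; see `docs/methods.md` for the generative model.

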