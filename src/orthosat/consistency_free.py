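"""Consistency of a constraint graph with an *unknown* species tree.

Questions answered here: is there *some* species tree S such that a
realization of the constraint graph is satisfied by a DS-tree consistent
with S?  Two constraint classes are always consistent (orthology-only and
paralogy-only sets, via star constructions).  For full graphs the answer is
characterized by the mandatory triplet set P3(R): species triplets
s(x)s(y)|s(z) read off induced paths x–z–y (orthology edges zx, zy, paralogy
non-edge xy, distinct grouped species); R is consistent iff some species
tree displays all of P3(R), decided by the classic BUILD (Aho) supertree
recursion.  For partial graphs a branch-and-bound explores realizations of
U, pruning on BUILD failure of the current P3 set and on unsatisfiability;
forced-edge preprocessing can resolve unknown pairs whose value is implied
by every P4 completion or by a P3 triplet contradiction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .constraint_graph import (
    ConstraintGraph,
    FullConstraintGraph,
    GeneFamily,
    Pair,
    find_induced_P4,
    pair,
)
from .consistency_fixed import CONSISTENT, INCONSISTENT, build_consistent_ds_tree
from .event_trees import (
    DSTree,
    DUP,
    SPEC,
    SpeciesTree,
    TreeNode,
    Triplet,
    is_consistent,
)
from .satisfiability import SatResult, build_ds_tree

__all__ = [
    "ConsResult",
    "SearchBudgetExceeded",
    "extract_p3",
    "build_species_tree",
    "orthology_only_witness",
    "paralogy_only_witness",
    "check_consistency_full",
    "check_cons",
    "preprocess_forced_edges",
    "PreprocessResult",
]


@dataclass
class ConsResult:
    """Outcome of a consistency check with an unknown species tree.

    When consistent, ``species_tree`` is a witness species tree,
    ``realization`` the chosen full constraint graph, and ``witness`` a
    DS-tree satisfying the input and consistent with ``species_tree``.
    """

    status: str
    species_tree: Optional[SpeciesTree] = None
    realization: Optional[FullConstraintGraph] = None
    witness: Optional[DSTree] = None
    forced: dict[Pair, str] = field(default_factory=dict)
    nodes_explored: int = 0

    def __bool__(self) -> bool:
        return self.status == CONSISTENT


class SearchBudgetExceeded(RuntimeError):
    """The branch-and-bound exceeded its node budget; no verdict was reached."""


# ---------------------------------------------------------------------------
# Mandatory triplets and the BUILD supertree recursion
# ---------------------------------------------------------------------------


def extract_p3(r: ConstraintGraph) -> set[Triplet]:
    """Species triplets forced by induced paths x–z–y of the constraint graph.

    For every gene triple with zx, zy in E, xy a paralogy non-edge (not in E
    or U) and s(x) != s(y), any satisfying DS-tree must contain the
    speciation triplet s(x)s(y)|s(z).
    """
    sp = r.family.species_of
    adj = r.adjacency(r.E)
    eu = r.E | r.U
    out: set[Triplet] = set()
    for z in r.family.genes:
        nbrs = sorted(adj[z])
        for x, y in itertools.combinations(nbrs, 2):
            if pair(x, y) in eu:
                continue
            if sp[x] != sp[y]:
                out.add(Triplet.make(sp[x], sp[y], sp[z]))
    return out


def build_species_tree(
    triplets: Iterable[Triplet], all_species: Iterable[str]
) -> Optional[SpeciesTree]:
    """BUILD (Aho) recursion: a species tree displaying every triplet, or None.

    The output is least-resolved in flavor: unconstrained splits stay
    non-binary and species unmentioned by any triplet attach as extra
    children wherever they are free.  Returns None iff no tree on
    ``all_species`` displays all triplets.
    """
    species = sorted(set(all_species))
    tset = set(triplets)
    for t in tset:
        if t.out in (t.a, t.b):
            return None  # undisplayable by any tree
        for label in t:
            if label not in species:
                raise KeyError(f"triplet label {label!r} not among the species")

    def rec(labels: frozenset[str], trips: list[Triplet]) -> Optional[TreeNode]:
        if len(labels) == 1:
            (sp,) = labels
            return TreeNode(label=sp)
        g = nx.Graph()
        g.add_nodes_from(labels)
        for t in trips:
            g.add_edge(t.a, t.b)
        comps = sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
        if len(comps) == 1:
            return None
        children = []
        for comp in comps:
            sub = [t for t in trips if t.a in comp and t.b in comp and t.out in comp]
            child = rec(comp, sub)
            if child is None:
                return None
            children.append(child)
        return TreeNode(children=children)

    root = rec(frozenset(species), sorted(tset))
    if root is None:
        return None
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# Always-consistent special cases
# ---------------------------------------------------------------------------


def _star_species_tree(species: Iterable[str]) -> SpeciesTree:
    species = sorted(set(species))
    if len(species) == 1:
        return SpeciesTree(TreeNode(label=species[0]))
    return SpeciesTree(TreeNode(children=[TreeNode(label=s) for s in species]))


def _dup_star(genes: Sequence[str]) -> TreeNode:
    if len(genes) == 1:
        return TreeNode(label=genes[0])
    return TreeNode(event=DUP, children=[TreeNode(label=g) for g in sorted(genes)])


def orthology_only_witness(
    family: GeneFamily, graph: Optional[ConstraintGraph] = None
) -> ConsResult:
    """Witness for an orthology-only constraint set: always consistent.

    Per-species duplication stars joined under a single speciation root make
    every cross-species pair orthologous and every same-species pair
    paralogous; the star species tree is consistent with it.  When ``graph``
    is given, its only paralogy non-edges must be same-species pairs (i.e.
    the constraints carry no cross-species paralogy).
    """
    sp = family.species_of
    if graph is not None:
        eu = graph.E | graph.U
        bad = [p for p in family.cross_species_pairs() if p not in eu]
        if bad:
            raise ValueError(f"cross-species paralogy constraints present: {bad[:3]}")
    by_species: dict[str, list[str]] = {}
    for g in family.genes:
        by_species.setdefault(sp[g], []).append(g)
    stars = [_dup_star(genes) for _, genes in sorted(by_species.items())]
    if len(stars) == 1:
        root = stars[0]
    else:
        root = TreeNode(event=SPEC, children=stars)
    witness = DSTree(root)
    stree = _star_species_tree(family.species)
    realization = FullConstraintGraph(
        family, frozenset(family.cross_species_pairs()), frozenset()
    )
    return ConsResult(
        status=CONSISTENT, species_tree=stree, realization=realization, witness=witness
    )


def paralogy_only_witness(
    family: GeneFamily, graph: Optional[ConstraintGraph] = None
) -> ConsResult:
    """Witness for a paralogy-only constraint set (E = ∅): always consistent.

    The all-duplication star over the genes satisfies the empty realization
    and is consistent with the star species tree.
    """
    if graph is not None and graph.E:
        raise ValueError("paralogy-only witness requires E = ∅")
    witness = DSTree(_dup_star(list(family.genes)))
    stree = _star_species_tree(family.species)
    realization = FullConstraintGraph(family, frozenset(), frozenset())
    return ConsResult(
        status=CONSISTENT, species_tree=stree, realization=realization, witness=witness
    )


# ---------------------------------------------------------------------------
# Full graphs: the P3 characterization
# ---------------------------------------------------------------------------


def check_consistency_full(r: FullConstraintGraph) -> ConsResult:
    """Consistency of a full graph: some species tree displays all of P3(R).

    Unsatisfiable graphs are inconsistent outright.  On success the returned
    species tree displays P3(R) and the witness DS-tree (built against that
    tree) satisfies R and is consistent with it.
    """
    if r.U:
        raise ValueError("check_consistency_full requires a full graph (U = ∅)")
    r.require_valid()
    sat = build_ds_tree(r)
    if not sat:
        return ConsResult(status=INCONSISTENT)
    stree = build_species_tree(extract_p3(r), r.family.species)
    if stree is None:
        return ConsResult(status=INCONSISTENT)
    fixed = build_consistent_ds_tree(r, stree)
    assert fixed, "internal: P3-displaying species tree must admit a witness"
    return ConsResult(
        status=CONSISTENT, species_tree=stree, realization=r, witness=fixed.witness
    )


# ---------------------------------------------------------------------------
# Forced-edge preprocessing
# ---------------------------------------------------------------------------


@dataclass
class PreprocessResult:
    """Fixpoint of the forced-edge rules.

    ``graph`` is the reduced constraint graph, ``forced`` maps resolved
    unknown pairs to ``"orthology"``/``"paralogy"``;  ``contradiction`` names
    a pair forced both ways (the graph is then inconsistent).
    """

    graph: ConstraintGraph
    forced: dict[Pair, str]
    contradiction: Optional[Pair] = None

    def __bool__(self) -> bool:
        return self.contradiction is None


def _induces_p4(quad: Sequence[str], edges: set[Pair]) -> bool:
    present = [p for p in itertools.combinations(sorted(quad), 2) if pair(*p) in edges]
    if len(present) != 3:
        return False
    deg: dict[str, int] = {v: 0 for v in quad}
    for x, y in present:
        deg[x] += 1
        deg[y] += 1
    return sorted(deg.values()) == [1, 1, 2, 2]


def preprocess_forced_edges(r: ConstraintGraph) -> PreprocessResult:
    """Resolve unknown pairs whose value is implied, repeated to a fixpoint.

    Rule a: a 4-subset spanning exactly one unknown pair where one assignment
    of that pair leaves an induced P4 on those four vertices under every
    completion (there is none left to complete) forces the other assignment;
    both assignments bad is a contradiction.

    Rule b: an induced path x–z–y (zx, zy in E) with xy unknown, where
    resolving xy to paralogy would create a species triplet contradicting a
    triplet already in P3(R) on the same three species, forces xy to
    orthology.
    """
    r = r.normalize()
    forced: dict[Pair, str] = {}
    graph = r
    changed = True
    while changed:
        changed = False
        sp = graph.family.species_of
        e_set = set(graph.E)
        u_set = set(graph.U)
        genes = sorted(graph.family.genes)

        def force(p: Pair, value: str) -> Optional[Pair]:
            prev = forced.get(p)
            if prev is not None and prev != value:
                return p
            forced[p] = value
            return None

        assignments: dict[Pair, str] = {}

        def propose(p: Pair, value: str) -> bool:
            """Record a forced value; False on an intra-pass conflict."""
            prev = assignments.get(p)
            if prev is not None and prev != value:
                return False
            assignments[p] = value
            return True

        # rule a: 4-sets with exactly one unknown pair
        for p in sorted(u_set):
            others = [g for g in genes if g not in p]
            for c, d in itertools.combinations(others, 2):
                quad = (p[0], p[1], c, d)
                quad_pairs = [pair(*q) for q in itertools.combinations(quad, 2)]
                if sum(q in u_set for q in quad_pairs) != 1:
                    continue
                base = {q for q in quad_pairs if q in e_set}
                p4_with = _induces_p4(quad, base | {p})
                p4_without = _induces_p4(quad, base)
                if p4_with and p4_without:
                    return PreprocessResult(graph=graph, forced=forced, contradiction=p)
                if p4_with and not p4_without:
                    if not propose(p, "paralogy"):
                        return PreprocessResult(graph=graph, forced=forced, contradiction=p)
                elif p4_without and not p4_with:
                    if not propose(p, "orthology"):
                        return PreprocessResult(graph=graph, forced=forced, contradiction=p)
        # rule b: P3 patterns blocked only by an unknown chord
        p3 = extract_p3(graph)
        topo_by_species: dict[frozenset[str], set[Triplet]] = {}
        for t in p3:
            topo_by_species.setdefault(frozenset(t), set()).add(t)
        adj = graph.adjacency(graph.E)
        for z in genes:
            for x, y in itertools.combinations(sorted(adj[z]), 2):
                p = pair(x, y)
                if p not in u_set or sp[x] == sp[y]:
                    continue
                would_be = Triplet.make(sp[x], sp[y], sp[z])
                rivals = topo_by_species.get(frozenset(would_be), ())
                if any(rv != would_be for rv in rivals):
                    if not propose(p, "orthology"):
                        return PreprocessResult(graph=graph, forced=forced, contradiction=p)
        for p, value in assignments.items():
            conflict = force(p, value)
            if conflict is not None:
                return PreprocessResult(graph=graph, forced=forced, contradiction=conflict)
        if assignments:
            new_e = set(graph.E)
            new_u = set(graph.U)
            for p, value in assignments.items():
                new_u.discard(p)
                if value == "orthology":
                    if sp[p[0]] == sp[p[1]]:
                        return PreprocessResult(
                            graph=graph, forced=forced, contradiction=p
                        )
                    new_e.add(p)
            graph = ConstraintGraph(graph.family, frozenset(new_e), frozenset(new_u))
            changed = True
    return PreprocessResult(graph=graph, forced=forced)


# ---------------------------------------------------------------------------
# Branch-and-bound for partial graphs
# ---------------------------------------------------------------------------


def _select_edge(graph: ConstraintGraph) -> Pair:
    """Prefer unknown pairs lying inside an induced P4 of R(∅); ties lexicographic."""
    p4 = find_induced_P4(graph.realize(frozenset()))
    if p4 is not None:
        quad = set(p4)
        candidates = sorted(p for p in graph.U if p[0] in quad and p[1] in quad)
        if candidates:
            return candidates[0]
    return min(graph.U)


def check_cons(
    r: ConstraintGraph,
    preprocess: bool = True,
    max_nodes: Optional[int] = None,
) -> ConsResult:
    """Exact consistency check for a partial constraint graph (unknown species tree).

    Branch-and-bound over the unknown pairs: each search node runs BUILD on
    the current P3 set (prune on failure — P3 only grows along a branch) and
    the satisfiability recursion with remaining unknowns as wildcards (prune
    on failure).  When no unknowns remain the full-graph characterization
    closes the branch.  The orthology assignment of the selected pair is
    tried first.  Worst-case exponential in |U|.

    ``max_nodes`` bounds the number of search nodes; exceeding it raises
    :class:`SearchBudgetExceeded` rather than returning a wrong verdict.
    """
    r.require_valid()
    r = r.normalize()
    forced: dict[Pair, str] = {}
    if preprocess:
        pre = preprocess_forced_edges(r)
        if not pre:
            return ConsResult(status=INCONSISTENT, forced=pre.forced)
        r = pre.graph
        forced = pre.forced
    counter = 0
    species = r.family.species

    def search(graph: ConstraintGraph) -> Optional[ConsResult]:
        nonlocal counter
        counter += 1
        if max_nodes is not None and counter > max_nodes:
            raise SearchBudgetExceeded(f"exceeded {max_nodes} search nodes")
        stree = build_species_tree(extract_p3(graph), species)
        if stree is None:
            return None
        if not build_ds_tree(graph):
            return None
        if not graph.U:
            full = FullConstraintGraph(graph.family, graph.E, frozenset())
            fixed = build_consistent_ds_tree(full, stree)
            assert fixed, "internal: BUILD tree must admit a witness for a full graph"
            return ConsResult(
                status=CONSISTENT,
                species_tree=stree,
                realization=full,
                witness=fixed.witness,
            )
        e = _select_edge(graph)
        as_orth = ConstraintGraph(graph.family, graph.E | {e}, graph.U - {e})
        if graph.family.species_of[e[0]] != graph.family.species_of[e[1]]:
            res = search(as_orth)
            if res is not None:
                return res
        as_para = ConstraintGraph(graph.family, graph.E, graph.U - {e})
        return search(as_para)

    result = search(r)
    if result is None:
        return ConsResult(status=INCONSISTENT, forced=forced, nodes_explored=counter)
    result.forced = forced
    result.nodes_explored = counter
    return result
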