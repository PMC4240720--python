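"""Satisfiability of a constraint graph: is there a DS-tree inducing the constraints?

A full constraint graph is satisfiable exactly when its orthology graph is a
cograph (P4-free); for partial graphs the question is the graph sandwich
problem for P4-free graphs.  Both are decided by one recursion: a vertex set
is satisfiable iff it is a single gene, or the empty realization R(∅) is
disconnected (its components can be joined under a duplication node), or the
complement of the full realization R(U) is disconnected (join under a
speciation node).  The recursion both decides satisfiability and builds a
witness DS-tree in O(n^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .constraint_graph import (
    ConstraintGraph,
    FullConstraintGraph,
    Pair,
    _bfs_components,
    complement_components,
    find_induced_P4,
    pair,
)
from .event_trees import DSTree, DUP, SPEC, TreeNode

__all__ = ["SatResult", "build_ds_tree", "is_satisfiable_full"]

SATISFIABLE = "satisfiable"
UNSATISFIABLE = "unsatisfiable"


@dataclass
class SatResult:
    """Outcome of a satisfiability check.

    ``witness`` is a DS-tree satisfying the graph when satisfiable;
    ``chosen_realization`` lists the unknown pairs the witness resolves to
    orthology (so the witness satisfies ``R(chosen_realization)`` exactly);
    ``failed_subset`` is the vertex set at which the recursion halted when
    unsatisfiable, for diagnostics.
    """

    status: str
    witness: Optional[DSTree] = None
    chosen_realization: frozenset[Pair] = frozenset()
    failed_subset: Optional[frozenset[str]] = None

    def __bool__(self) -> bool:
        return self.status == SATISFIABLE


class _Unsat(Exception):
    def __init__(self, vertices: frozenset[str]):
        self.vertices = vertices


def _subset_components(vertices, adj):
    return _bfs_components(vertices, adj)


def _recurse(vertices: frozenset[str], e_adj, eu_adj) -> TreeNode:
    if len(vertices) == 1:
        (gene,) = vertices
        return TreeNode(label=gene)
    comps = _subset_components(vertices, e_adj)
    if len(comps) > 1:
        event = DUP
    else:
        comps = complement_components(vertices, eu_adj)
        if len(comps) == 1:
            raise _Unsat(vertices)
        event = SPEC
    return TreeNode(event=event, children=[_recurse(c, e_adj, eu_adj) for c in comps])


def build_ds_tree(r: ConstraintGraph) -> SatResult:
    """Decide satisfiability and construct a witness DS-tree.

    The witness is a non-binary star-join exactly as the disconnection
    recursion produces it: duplication nodes over components of R(∅),
    speciation nodes over co-components of R(U).  Duplication splits are
    preferred when both apply.
    """
    r.require_valid()
    r = r.normalize()
    if not r.family.genes:
        raise ValueError("empty gene family")
    e_adj = r.adjacency(r.E)
    eu_adj = r.adjacency(r.E | r.U)
    try:
        root = _recurse(frozenset(r.family.genes), e_adj, eu_adj)
    except _Unsat as u:
        return SatResult(status=UNSATISFIABLE, failed_subset=u.vertices)
    witness = DSTree(root)
    chosen = frozenset(p for p in r.U if witness.relation(*p) == "orthologous")
    return SatResult(status=SATISFIABLE, witness=witness, chosen_realization=chosen)


def is_satisfiable_full(r: FullConstraintGraph) -> bool:
    """Cograph route for full graphs: satisfiable iff the graph is P4-free."""
    if r.U:
        raise ValueError("is_satisfiable_full requires a full graph (U = ∅)")
    return find_induced_P4(r) is None
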