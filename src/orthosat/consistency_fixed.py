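"""Consistency of a constraint graph with a *given* species tree.

The satisfiability recursion extends to a fixed species tree S: a duplication
split needs no species-level justification, but a speciation split is only
allowed when the co-components of R(U) can be grouped into a *speciation
partition* — parts whose species-level lcas are pairwise unrelated in S.  The
canonical partition is found by a preorder traversal of S: each part collects
the components whose species-lca falls inside the subtree of the part's
shallowest representative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .constraint_graph import (
    ConstraintGraph,
    Pair,
    _bfs_components,
    complement_components,
)
from .event_trees import DSTree, DUP, SPEC, SpeciesTree, TreeNode, is_consistent
from .satisfiability import SatResult

__all__ = [
    "CONSISTENT",
    "INCONSISTENT",
    "ConsFixedResult",
    "SpeciationPartition",
    "find_speciation_partition",
    "build_consistent_ds_tree",
]

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"


@dataclass
class SpeciationPartition:
    """A non-trivial grouping of complement-graph components licensing a speciation root.

    Each part is a list of components (gene sets); distinct parts have
    species-level lcas unrelated in the species tree.
    """

    parts: list[list[frozenset[str]]]

    def __post_init__(self):
        if len(self.parts) < 2:
            raise ValueError("a speciation partition must have at least two parts")

    def part_gene_sets(self) -> list[frozenset[str]]:
        return [frozenset().union(*part) for part in self.parts]


@dataclass
class ConsFixedResult:
    """Outcome of a consistency-with-S check; mirrors :class:`SatResult`."""

    status: str
    witness: Optional[DSTree] = None
    chosen_realization: frozenset[Pair] = frozenset()
    failed_subset: Optional[frozenset[str]] = None

    def __bool__(self) -> bool:
        return self.status == CONSISTENT


def find_speciation_partition(
    components: Sequence[frozenset[str]],
    s: SpeciesTree,
    species_of: Mapping[str, str],
) -> Optional[SpeciationPartition]:
    """Group components by a preorder traversal of the species tree.

    Components whose species-lca lies in the subtree below the shallowest
    lca met so far (on the current root-to-node path) join that part; a new
    part opens whenever a component's lca is met outside every open part.
    Returns None when the grouping is trivial (a single part).
    """
    unknown = {
        species_of[g] for comp in components for g in comp
    } - s.leaf_labels
    if unknown:
        raise KeyError(f"species absent from the species tree: {sorted(unknown)}")
    by_node: dict[int, list[frozenset[str]]] = {}
    for comp in sorted(components, key=min):
        node = s.lca({species_of[g] for g in comp})
        by_node.setdefault(id(node), []).append(comp)

    parts: list[list[frozenset[str]]] = []

    def visit(node: TreeNode, current: Optional[list[frozenset[str]]]) -> None:
        here = by_node.get(id(node))
        if here:
            if current is None:
                current = []
                parts.append(current)
            current.extend(here)
        for child in node.children:
            visit(child, current)

    visit(s.root, None)
    if len(parts) < 2:
        return None
    parts.sort(key=lambda part: min(min(c) for c in part))
    return SpeciationPartition(parts)


class _Inconsistent(Exception):
    def __init__(self, vertices: frozenset[str]):
        self.vertices = vertices


def build_consistent_ds_tree(r: ConstraintGraph, s: SpeciesTree) -> ConsFixedResult:
    """Decide consistency with the species tree ``s`` and build a witness DS-tree.

    Recursion: a single gene is a leaf; otherwise a duplication node over the
    components of R(∅) when disconnected (tried first), else a speciation
    node over the parts of a speciation partition of the co-components of
    R(U).  If the duplication branch fails, the speciation branch is still
    attempted before declaring inconsistency (the characterization is a
    disjunction of the two conditions).
    """
    r.require_valid()
    r = r.normalize()
    if not r.family.genes:
        raise ValueError("empty gene family")
    species_of = r.family.species_of
    missing = set(species_of[g] for g in r.family.genes) - s.leaf_labels
    if missing:
        raise KeyError(f"species absent from the species tree: {sorted(missing)}")
    e_adj = r.adjacency(r.E)
    eu_adj = r.adjacency(r.E | r.U)

    def recurse(vertices: frozenset[str]) -> TreeNode:
        if len(vertices) == 1:
            (gene,) = vertices
            return TreeNode(label=gene)
        comps = _bfs_components(vertices, e_adj)
        if len(comps) > 1:
            try:
                return TreeNode(event=DUP, children=[recurse(c) for c in comps])
            except _Inconsistent:
                pass
        co_comps = complement_components(vertices, eu_adj)
        if len(co_comps) > 1:
            partition = find_speciation_partition(co_comps, s, species_of)
            if partition is not None:
                children = [recurse(part) for part in partition.part_gene_sets()]
                return TreeNode(event=SPEC, children=children)
        raise _Inconsistent(vertices)

    try:
        root = recurse(frozenset(r.family.genes))
    except _Inconsistent as exc:
        return ConsFixedResult(status=INCONSISTENT, failed_subset=exc.vertices)
    witness = DSTree(root)
    assert is_consistent(witness, s, species_of), "internal audit: witness not consistent"
    chosen = frozenset(p for p in r.U if witness.relation(*p) == "orthologous")
    return ConsFixedResult(status=CONSISTENT, witness=witness, chosen_realization=chosen)
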