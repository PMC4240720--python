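"""Edge-bicoloured constraint graphs over a gene family.

A constraint graph ``R = (V, E, U)`` records partial knowledge about pairwise
homology relations inside a gene family: vertices are genes, ``E`` holds pairs
constrained to be orthologs, pairs outside ``E`` and ``U`` are constrained to
be paralogs (paralogy non-edges), and ``U`` marks pairs whose relation is
unknown.  Choosing ``F ⊆ U`` as extra orthology edges yields the *realization*
``R(F)``, a full graph with no unknowns — deciding whether some realization is
a cograph is exactly the graph sandwich problem for P4-free graphs.

Two genes of the same species can never be orthologs (they descend from a
duplication within that species), so same-species pairs in ``E`` are invalid
and same-species pairs in ``U`` normalize to paralogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "Pair",
    "pair",
    "GeneFamily",
    "ConstraintGraph",
    "FullConstraintGraph",
    "components",
    "complement_components",
    "find_induced_P4",
    "combine",
]

Pair = tuple[str, str]


def pair(x: str, y: str) -> Pair:
    """Canonical unordered pair: lexicographically smaller gene first."""
    if x == y:
        raise ValueError(f"self-pair {x!r}")
    return (x, y) if x < y else (y, x)


@dataclass(frozen=True)
class GeneFamily:
    """An ordered set of gene identifiers with a total gene -> species map."""

    genes: tuple[str, ...]
    species_of: Mapping[str, str]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        missing = [g for g in self.genes if g not in self.species_of]
        if missing:
            raise ValueError(f"genes without a species: {missing}")

    @classmethod
    def from_mapping(cls, species_of: Mapping[str, str]) -> "GeneFamily":
        return cls(tuple(sorted(species_of)), dict(species_of))

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.species_of[g] for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.species_of and gene in self.genes

    def pairs(self) -> Iterator[Pair]:
        ordered = sorted(self.genes)
        for i, x in enumerate(ordered):
            for y in ordered[i + 1 :]:
                yield (x, y)

    def cross_species_pairs(self) -> Iterator[Pair]:
        for x, y in self.pairs():
            if self.species_of[x] != self.species_of[y]:
                yield (x, y)

    def restrict(self, genes: Iterable[str]) -> "GeneFamily":
        keep = set(genes)
        unknown = keep - set(self.genes)
        if unknown:
            raise KeyError(f"genes not in family: {sorted(unknown)}")
        return GeneFamily(
            tuple(g for g in self.genes if g in keep),
            {g: self.species_of[g] for g in keep},
        )


@dataclass(frozen=True)
class ConstraintGraph:
    """``R = (V, E, U)``: orthology edges ``E``, unknown edges ``U``; paralogy implicit."""

    family: GeneFamily
    E: frozenset[Pair] = frozenset()
    U: frozenset[Pair] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "E", frozenset(self.E))
        object.__setattr__(self, "U", frozenset(self.U))

    # -- invariants ----------------------------------------------------------

    def validate(self) -> list[str]:
        """Invariant violations, each naming the offending pair and rule; [] iff well formed."""
        violations = []
        genes = set(self.family.genes)
        sp = self.family.species_of
        for name, edges in (("E", self.E), ("U", self.U)):
            for p in sorted(edges):
                if len(p) != 2 or p[0] == p[1]:
                    violations.append(f"self-pair in {name}: {p}")
                    continue
                if p != pair(*p):
                    violations.append(f"non-canonical pair in {name}: {p}")
                if not (p[0] in genes and p[1] in genes):
                    violations.append(f"pair with endpoint outside family in {name}: {p}")
        for p in sorted(self.E & self.U):
            violations.append(f"pair in both E and U: {p}")
        for p in sorted(self.E):
            if p[0] in sp and p[1] in sp and sp[p[0]] == sp[p[1]]:
                violations.append(f"same-species orthology: {p}")
        return violations

    def require_valid(self) -> "ConstraintGraph":
        violations = self.validate()
        if violations:
            raise ValueError("invalid constraint graph: " + "; ".join(violations))
        return self

    def normalize(self) -> "ConstraintGraph":
        """Resolve same-species unknown pairs to paralogy (drop them from U)."""
        sp = self.family.species_of
        u = frozenset(p for p in self.U if sp[p[0]] != sp[p[1]])
        if u == self.U:
            return self
        return ConstraintGraph(self.family, self.E, u)

    # -- basic queries ---------------------------------------------------------

    @property
    def genes(self) -> tuple[str, ...]:
        return self.family.genes

    @property
    def is_full(self) -> bool:
        return not self.U

    def non_edges(self) -> frozenset[Pair]:
        """Paralogy non-edges: pairs absent from both E and U."""
        return frozenset(p for p in self.family.pairs() if p not in self.E and p not in self.U)

    def status(self, x: str, y: str) -> str:
        p = pair(x, y)
        if p in self.E:
            return "orthology"
        if p in self.U:
            return "unknown"
        return "paralogy"

    # -- operations ------------------------------------------------------------

    def realize(self, F: Iterable[Pair] = ()) -> "FullConstraintGraph":
        """Realization R(F): F ⊆ U becomes orthology, the rest of U becomes paralogy."""
        F = frozenset(F)
        if not F <= self.U:
            raise ValueError(f"realization set not contained in U: {sorted(F - self.U)}")
        return FullConstraintGraph(self.family, self.E | F, frozenset())

    def complement(self) -> "ConstraintGraph":
        """Swap orthology edges and paralogy non-edges; U is shared. An involution."""
        return ConstraintGraph(self.family, self.non_edges(), self.U)

    def induced(self, X: Iterable[str]) -> "ConstraintGraph":
        """R[X]: edges of E and U with both endpoints in X, family restricted to X."""
        keep = set(X)
        fam = self.family.restrict(keep)
        e = frozenset(p for p in self.E if p[0] in keep and p[1] in keep)
        u = frozenset(p for p in self.U if p[0] in keep and p[1] in keep)
        return type(self)(fam, e, u)

    def adjacency(self, edges: Optional[frozenset[Pair]] = None) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {g: set() for g in self.family.genes}
        for x, y in self.E if edges is None else edges:
            adj[x].add(y)
            adj[y].add(x)
        return adj


@dataclass(frozen=True)
class FullConstraintGraph(ConstraintGraph):
    """A constraint graph with no unknown pairs (U = ∅)."""

    def __post_init__(self):
        super().__post_init__()
        if self.U:
            raise ValueError("full constraint graph must have U = ∅")


# ---------------------------------------------------------------------------
# Graph-structure helpers
# ---------------------------------------------------------------------------


def _bfs_components(vertices: Iterable[str], adj: Mapping[str, set[str]]) -> list[frozenset[str]]:
    todo = set(vertices)
    comps = []
    while todo:
        start = next(iter(todo))
        seen = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in adj[v] & todo:
                if w not in seen:
                    seen.add(w)
                    frontier.append(w)
        todo -= seen
        comps.append(frozenset(seen))
    return sorted(comps, key=min)


def components(graph: ConstraintGraph) -> list[frozenset[str]]:
    """Connected components of a full graph under E, sorted by smallest member."""
    if graph.U:
        raise ValueError("components is defined for full graphs (U = ∅)")
    return _bfs_components(graph.family.genes, graph.adjacency())


def complement_components(
    vertices: Iterable[str], adj: Mapping[str, set[str]]
) -> list[frozenset[str]]:
    """Connected components of the complement of the given adjacency, without
    materializing the complement (linear-time unvisited-set BFS)."""
    rest = set(vertices)
    comps = []
    while rest:
        start = rest.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            reach = rest - adj[v]
            rest -= reach
            comp |= reach
            frontier.extend(reach)
        comps.append(frozenset(comp))
    return sorted(comps, key=min)


def find_induced_P4(graph: ConstraintGraph) -> Optional[tuple[str, str, str, str]]:
    """An ordered 4-tuple (a,b,c,d) inducing a path a-b-c-d in a full graph, or None.

    None iff the graph is a cograph.  Searches over candidate middle edges
    (b,c): the ends a, d must satisfy a ∈ N(b)\\N(c), d ∈ N(c)\\N(b), ad not
    an edge — exactly the six-pair pattern of an induced P4.
    """
    if graph.U:
        raise ValueError("find_induced_P4 is defined for full graphs (U = ∅)")
    adj = graph.adjacency()
    for b, c in sorted(graph.E):
        for bb, cc in ((b, c), (c, b)):
            a_side = sorted(adj[bb] - adj[cc] - {cc})
            d_side = sorted(adj[cc] - adj[bb] - {bb})
            for a in a_side:
                for d in d_side:
                    if a != d and d not in adj[a]:
                        return (a, bb, cc, d)
    return None


def combine(r1: FullConstraintGraph, r2: FullConstraintGraph) -> ConstraintGraph:
    """Merge two full graphs, keeping only relations they agree on.

    Common orthology edges stay in E, common non-edges stay paralogy
    non-edges, and every pair on which the two graphs disagree becomes an
    unknown edge.
    """
    if r1.U or r2.U:
        raise ValueError("combine is defined for full graphs (U = ∅)")
    if r1.family != r2.family:
        raise ValueError("combine requires identical gene families")
    return ConstraintGraph(r1.family, r1.E & r2.E, r1.E ^ r2.E)
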