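"""Rooted trees, species trees and event-labeled gene trees (DS-trees).

A *DS-tree* is a rooted gene tree in which every internal node is labeled
``Dup`` (duplication) or ``Spec`` (speciation).  It encodes a candidate
evolutionary scenario for a gene family without reference to a species tree:
two genes are *orthologs* when their least common ancestor is a speciation
node and *paralogs* when it is a duplication node.  A DS-tree is *consistent*
with a species tree when every speciation node groups genes in a way the
species phylogeny allows; equivalently, when the species tree displays every
speciation triplet of the gene tree.  Both routes are implemented here and
must agree (see :func:`is_consistent` and :func:`is_consistent_by_triplets`).

Trees may be non-binary: the constructions used elsewhere in the package
deliberately create star nodes, and species trees are not assumed binary.
Tree equality throughout is label-isomorphism ignoring child order.
"""

from __future__ import annotations

import io
import re
from typing import Callable, Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

import dendropy

__all__ = [
    "DUP",
    "SPEC",
    "TreeNode",
    "RootedTree",
    "SpeciesTree",
    "DSTree",
    "Triplet",
    "satisfies",
    "is_consistent",
    "is_consistent_by_triplets",
    "parse_newick",
    "parse_species_tree",
    "parse_ds_tree",
]

DUP = "Dup"
SPEC = "Spec"

_EVENT_ALIASES = {
    "D": DUP,
    "DUP": DUP,
    "DUPLICATION": DUP,
    "S": SPEC,
    "SPEC": SPEC,
    "SPECIATION": SPEC,
}


class TreeNode:
    """A node of a rooted tree; leaves carry a label, internal nodes may carry an event."""

    __slots__ = ("label", "event", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        event: Optional[str] = None,
        children: Iterable["TreeNode"] = (),
    ):
        self.label = label
        self.event = event
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        for child in children:
            self.add_child(child)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> Iterator["TreeNode"]:
        return (n for n in self.preorder() if n.is_leaf)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"TreeNode({self.label!r})"
        return f"TreeNode(event={self.event!r}, n_children={len(self.children)})"


class Triplet(NamedTuple):
    """A rooted binary three-leaf topology ``ab|out`` (``a < b`` lexicographically)."""

    a: str
    b: str
    out: str

    @classmethod
    def make(cls, x: str, y: str, z: str) -> "Triplet":
        a, b = sorted((x, y))
        return cls(a, b, z)

    def __str__(self) -> str:
        return f"{self.a}{self.b}|{self.out}"


class RootedTree:
    """A rooted tree with uniquely labeled leaves.

    Internal nodes may have any out-degree >= 2; unary internal nodes are
    rejected.  Instances are treated as immutable after construction (ancestry
    indices are cached).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _index(self) -> None:
        self._depth: dict[int, int] = {}
        self._tin: dict[int, int] = {}
        self._tout: dict[int, int] = {}
        self._leaf_by_label: dict[str, TreeNode] = {}
        clock = 0
        stack: list[tuple[TreeNode, int, bool]] = [(self.root, 0, False)]
        while stack:
            node, depth, done = stack.pop()
            if done:
                self._tout[id(node)] = clock
                clock += 1
                continue
            self._depth[id(node)] = depth
            self._tin[id(node)] = clock
            clock += 1
            stack.append((node, depth, True))
            for child in reversed(node.children):
                stack.append((child, depth + 1, False))
            if node.is_leaf:
                if node.label is None:
                    raise ValueError("leaf without label")
                if node.label in self._leaf_by_label:
                    raise ValueError(f"duplicate leaf label {node.label!r}")
                self._leaf_by_label[node.label] = node

    def _validate(self) -> None:
        for node in self.root.preorder():
            if not node.is_leaf and len(node.children) == 1:
                raise ValueError("internal node of out-degree 1")

    # -- basic queries -------------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self._leaf_by_label)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_by_label)

    def node_of(self, label: str) -> TreeNode:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise KeyError(f"unknown leaf label {label!r}") from None

    def depth(self, node: TreeNode) -> int:
        return self._depth[id(node)]

    def is_ancestor_or_equal(self, a: TreeNode, b: TreeNode) -> bool:
        """True iff ``a`` is ``b`` or an ancestor of ``b``."""
        return self._tin[id(a)] <= self._tin[id(b)] and self._tout[id(b)] <= self._tout[id(a)]

    def unrelated(self, a: TreeNode, b: TreeNode) -> bool:
        """True iff the nodes differ and neither is an ancestor of the other."""
        if a is b:
            return False
        return not self.is_ancestor_or_equal(a, b) and not self.is_ancestor_or_equal(b, a)

    def lca_pair(self, a: TreeNode, b: TreeNode) -> TreeNode:
        da, db = self._depth[id(a)], self._depth[id(b)]
        while da > db:
            a = a.parent  # type: ignore[assignment]
            da -= 1
        while db > da:
            b = b.parent  # type: ignore[assignment]
            db -= 1
        while a is not b:
            a = a.parent  # type: ignore[assignment]
            b = b.parent  # type: ignore[assignment]
        return a

    def lca(self, labels: Iterable[str]) -> TreeNode:
        """Least common ancestral node of a nonempty set of leaf labels."""
        it = iter(labels)
        try:
            node = self.node_of(next(it))
        except StopIteration:
            raise ValueError("lca of an empty leaf set") from None
        for label in it:
            node = self.lca_pair(node, self.node_of(label))
        return node

    # -- structural operations -----------------------------------------------

    def copy(self) -> "RootedTree":
        return type(self)(_copy_node(self.root))

    def restrict(self, labels: Iterable[str]) -> "RootedTree":
        """Restriction to a nonempty leaf subset.

        The result is rooted at the least common ancestor of the subset;
        internal nodes left with a single child are suppressed (the root is
        kept as-is).  Event labels are inherited by surviving nodes.
        """
        keep = set(labels)
        if not keep:
            raise ValueError("restriction to an empty leaf set")
        missing = keep - self.leaf_labels
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        top = self.lca(keep)

        def prune(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.label in keep:
                    return TreeNode(label=node.label)
                return None
            kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            return TreeNode(event=node.event, children=kept)

        new_root = prune(top)
        assert new_root is not None
        return type(self)(new_root)

    def canonical_form(self) -> tuple:
        """Order-independent canonical key; equal keys <=> label-isomorphic trees."""

        def key(node: TreeNode) -> tuple:
            if node.is_leaf:
                return ("leaf", node.label)
            return (node.event, tuple(sorted((key(c) for c in node.children), key=repr)))

        return key(self.root)

    def is_isomorphic(self, other: "RootedTree") -> bool:
        """Label-isomorphism ignoring child order (event labels compared when present)."""
        return self.canonical_form() == other.canonical_form()

    def displays(self, small: "RootedTree") -> bool:
        """True iff restricting to the small tree's leaves is label-isomorphic to it."""
        if not small.leaf_labels <= self.leaf_labels:
            raise KeyError("displayed tree has leaves absent from the larger tree")
        return self.restrict(small.leaf_labels).is_isomorphic(small)

    def displays_triplet(self, t: Triplet) -> bool:
        """True iff the tree displays the rooted triplet ``t.a t.b | t.out``."""
        if t.out in (t.a, t.b):
            return False
        for label in t:
            if label not in self._leaf_by_label:
                raise KeyError(f"unknown leaf label {label!r}")
        inner = self.lca_pair(self.node_of(t.a), self.node_of(t.b))
        outer = self.lca_pair(inner, self.node_of(t.out))
        return inner is not outer

    def triplets(self) -> set[Triplet]:
        """All rooted triplets: 3-subsets of leaves whose restriction is binary."""
        labels = sorted(self._leaf_by_label)
        nodes = [self._leaf_by_label[x] for x in labels]
        n = len(labels)
        lcas = {}
        for i in range(n):
            for j in range(i + 1, n):
                lcas[i, j] = self.lca_pair(nodes[i], nodes[j])
        out: set[Triplet] = set()
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    hit = _triplet_topology(self, labels, lcas, i, j, k)
                    if hit is not None:
                        out.add(hit[0])
        return out

    # -- serialization ---------------------------------------------------------

    def newick(self, events: Optional[str] = None) -> str:
        """Serialize to Newick.

        ``events=None`` writes plain Newick (leaf labels only); ``"label"``
        writes internal node labels ``S``/``D``; ``"nhx"`` writes
        ``[&&NHX:Ev=Spec]`` / ``[&&NHX:Ev=Dup]`` comments.
        """
        buf = io.StringIO()
        _write_newick(self.root, buf, events)
        buf.write(";")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.newick(events='label')!r})"


class SpeciesTree(RootedTree):
    """A rooted, not necessarily binary tree whose leaves are species identifiers."""


class DSTree(RootedTree):
    """A rooted gene tree with every internal node labeled ``Dup`` or ``Spec``."""

    def _validate(self) -> None:
        super()._validate()
        for node in self.root.preorder():
            if not node.is_leaf and node.event not in (DUP, SPEC):
                raise ValueError("DS-tree internal node without Dup/Spec label")

    def relation(self, x: str, y: str) -> str:
        """``"orthologous"`` if the genes' lca is a speciation node, else ``"paralogous"``."""
        if x == y:
            raise ValueError("relation of a gene with itself is undefined")
        node = self.lca_pair(self.node_of(x), self.node_of(y))
        return "orthologous" if node.event == SPEC else "paralogous"

    def speciation_triplets(self, species_of: Mapping[str, str]) -> set[Triplet]:
        """Species triplets s(x)s(y)|s(z) for gene triplets xy|z rooted at a speciation.

        Only triplets with a binary restriction and s(x) != s(y) contribute;
        duplicates collapse.  Triplets whose outgroup species coincides with a
        grouped species are emitted as-is (they are undisplayable and will be
        rejected by any downstream supertree check).
        """
        labels = sorted(self._leaf_by_label)
        nodes = [self._leaf_by_label[x] for x in labels]
        n = len(labels)
        lcas = {}
        for i in range(n):
            for j in range(i + 1, n):
                lcas[i, j] = self.lca_pair(nodes[i], nodes[j])
        out: set[Triplet] = set()
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    hit = _triplet_topology(self, labels, lcas, i, j, k)
                    if hit is None:
                        continue
                    t, root = hit
                    if root.event != SPEC:
                        continue
                    sa, sb, sz = species_of[t.a], species_of[t.b], species_of[t.out]
                    if sa != sb:
                        out.add(Triplet.make(sa, sb, sz))
        return out

    def induced_orthology(self) -> frozenset[tuple[str, str]]:
        """All unordered gene pairs orthologous w.r.t. this tree."""
        labels = sorted(self._leaf_by_label)
        out = set()
        for i, x in enumerate(labels):
            for y in labels[i + 1 :]:
                if self.relation(x, y) == "orthologous":
                    out.add((x, y))
        return frozenset(out)


def _triplet_topology(tree, labels, lcas, i, j, k) -> Optional[tuple[Triplet, TreeNode]]:
    """Binary topology of 3-subset {labels[i|j|k]} plus its root, or None for a star.

    The root of a triplet xy|z is the lca of all three leaves; it carries the
    event label deciding speciation-triplet membership for DS-trees.
    """
    nij = lcas[i, j]
    nik = lcas[i, k]
    njk = lcas[j, k]
    dij, dik, djk = tree.depth(nij), tree.depth(nik), tree.depth(njk)
    if dij > dik and dij > djk:
        return Triplet.make(labels[i], labels[j], labels[k]), nik
    if dik > dij and dik > djk:
        return Triplet.make(labels[i], labels[k], labels[j]), nij
    if djk > dij and djk > dik:
        return Triplet.make(labels[j], labels[k], labels[i]), nij
    return None


def satisfies(g: DSTree, r) -> bool:
    """True iff the DS-tree induces every known constraint of the graph ``r``.

    Every orthology edge of ``r`` must be orthologous w.r.t. ``g`` and every
    paralogy non-edge paralogous; unknown pairs are unconstrained.  The leaf
    set must equal the gene family.
    """
    if g.leaf_labels != frozenset(r.family.genes):
        raise ValueError("DS-tree leaves must equal the constraint graph's gene set")
    for p in r.E:
        if g.relation(*p) != "orthologous":
            return False
    for p in r.non_edges():
        if g.relation(*p) != "paralogous":
            return False
    return True


# ---------------------------------------------------------------------------
# Consistency of a DS-tree with a species tree
# ---------------------------------------------------------------------------


def is_consistent(g: DSTree, s: SpeciesTree, species_of: Mapping[str, str]) -> bool:
    """Event-based consistency check.

    True iff for every speciation node and every two of its children, the
    species-level least common ancestors of the children's leaf sets are
    unrelated in ``s`` (distinct, neither ancestral to the other).
    """
    _require_species_present(g, s, species_of)
    # species set of each subtree, bottom-up
    spset: dict[int, frozenset[str]] = {}
    for node in g.root.postorder():
        if node.is_leaf:
            spset[id(node)] = frozenset((species_of[node.label],))
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= spset[id(child)]
            spset[id(node)] = frozenset(acc)
    for node in g.root.preorder():
        if node.is_leaf or node.event != SPEC:
            continue
        lcas = [s.lca(spset[id(child)]) for child in node.children]
        for i in range(len(lcas)):
            for j in range(i + 1, len(lcas)):
                if not s.unrelated(lcas[i], lcas[j]):
                    return False
    return True


def is_consistent_by_triplets(g: DSTree, s: SpeciesTree, species_of: Mapping[str, str]) -> bool:
    """Triplet-based consistency check: ``s`` displays every speciation triplet of ``g``.

    Agrees with :func:`is_consistent` on DS-trees respecting the trivial-paralogy
    assumption (no speciation node joins two copies of the same species).
    """
    _require_species_present(g, s, species_of)
    for t in g.speciation_triplets(species_of):
        if t.out in (t.a, t.b) or not s.displays_triplet(t):
            return False
    return True


def _require_species_present(g: DSTree, s: SpeciesTree, species_of: Mapping[str, str]) -> None:
    missing = {species_of[x] for x in g.leaf_labels} - s.leaf_labels
    if missing:
        raise KeyError(f"species absent from the species tree: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy; writing is plain serialization)
# ---------------------------------------------------------------------------

_SAFE_LABEL = re.compile(r"^[\w@.\-|]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _write_newick(node: TreeNode, buf: io.StringIO, events: Optional[str]) -> None:
    if node.is_leaf:
        buf.write(_quote(node.label or ""))
        return
    buf.write("(")
    for i, child in enumerate(node.children):
        if i:
            buf.write(",")
        _write_newick(child, buf, events)
    buf.write(")")
    if events == "label" and node.event:
        buf.write("S" if node.event == SPEC else "D")
    elif events == "nhx" and node.event:
        buf.write(f"[&&NHX:Ev={node.event}]")


def _copy_node(node: TreeNode) -> TreeNode:
    if node.is_leaf:
        return TreeNode(label=node.label)
    return TreeNode(event=node.event, children=[_copy_node(c) for c in node.children])


def _event_from_dendropy(nd: "dendropy.Node") -> Optional[str]:
    for comment in nd.comments or ():
        m = re.search(r"Ev=([A-Za-z]+)", comment)
        if m:
            return _EVENT_ALIASES.get(m.group(1).upper())
    if nd.label:
        return _EVENT_ALIASES.get(nd.label.strip().upper())
    return None


def parse_newick(text: str, with_events: bool = False) -> TreeNode:
    """Parse a single Newick tree into a :class:`TreeNode` topology.

    ``with_events=True`` interprets internal node labels ``S``/``D`` (or
    ``Spec``/``Dup``, any case) and NHX ``Ev=`` comments as event labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc

    def conv(nd: "dendropy.Node") -> TreeNode:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise ValueError("leaf without label in Newick input")
            return TreeNode(label=str(label))
        event = _event_from_dendropy(nd) if with_events else None
        return TreeNode(event=event, children=[conv(c) for c in nd.child_nodes()])

    root = conv(dtree.seed_node)
    # dendropy may keep a unary root (e.g. "(a);"); splice it away
    while not root.is_leaf and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    return root


def parse_species_tree(text: str) -> SpeciesTree:
    return SpeciesTree(parse_newick(text))


def parse_ds_tree(text: str) -> DSTree:
    return DSTree(parse_newick(text, with_events=True))
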