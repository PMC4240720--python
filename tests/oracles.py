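"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately simple and separate from the implementation:
graphs are bitmasks over the C(n,2) pair slots, trees are nested tuples, and
every decision is made by exhaustive enumeration (all 4-subsets, all
realizations, all rooted trees).  Nothing imports the package.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterable, Iterator, Optional, Sequence

# ---------------------------------------------------------------------------
# Bitmask graphs: vertex i<j pairs indexed lexicographically
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def pair_index(n: int) -> dict[tuple[int, int], int]:
    return {p: i for i, p in enumerate(itertools.combinations(range(n), 2))}


# 6-bit masks (pair order (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)) that are a P4
def _p4_masks() -> frozenset[int]:
    idx = pair_index(4)
    masks = set()
    for perm in itertools.permutations(range(4)):
        m = 0
        for a, b in zip(perm, perm[1:]):
            m |= 1 << idx[(min(a, b), max(a, b))]
        masks.add(m)
    return frozenset(masks)


P4_MASKS = _p4_masks()


@lru_cache(maxsize=None)
def _quad_tables(n: int) -> list[tuple[int, ...]]:
    """For each 4-subset of range(n), the 6 global pair-slot indices in local order."""
    idx = pair_index(n)
    tables = []
    for quad in itertools.combinations(range(n), 4):
        slots = tuple(idx[p] for p in itertools.combinations(quad, 2))
        tables.append(slots)
    return tables


def is_p4_free(mask: int, n: int) -> bool:
    """Exhaustive 4-subset scan of a full graph given as an edge bitmask."""
    for slots in _quad_tables(n):
        local = 0
        for k, s in enumerate(slots):
            if mask >> s & 1:
                local |= 1 << k
        if local in P4_MASKS:
            return False
    return True


def find_p4_exhaustive(n: int, edges: set[tuple[int, int]]) -> Optional[tuple[int, ...]]:
    """Some 4-subset inducing a path, by scanning all orderings of all subsets."""
    eset = {(min(p), max(p)) for p in edges}
    for quad in itertools.combinations(range(n), 4):
        for perm in itertools.permutations(quad):
            if perm[0] > perm[3]:
                continue
            a, b, c, d = perm
            want = {(min(a, b), max(a, b)), (min(b, c), max(b, c)), (min(c, d), max(c, d))}
            have = {p for p in itertools.combinations(sorted(quad), 2) if p in eset}
            if have == want:
                return perm
    return None


def submasks(mask: int) -> Iterator[int]:
    sub = mask
    while True:
        yield sub
        if sub == 0:
            return
        sub = (sub - 1) & mask


def satisfiable_bruteforce(e_mask: int, u_mask: int, n: int) -> bool:
    """Some realization (E plus a subset of U) is P4-free."""
    return any(is_p4_free(e_mask | f, n) for f in submasks(u_mask))


# ---------------------------------------------------------------------------
# Nested-tuple rooted trees; leaves are strings, internal nodes are
# (label, children) with children sorted for canonical form.
# ---------------------------------------------------------------------------


def _set_partitions(items: Sequence) -> Iterator[list[list]]:
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


@lru_cache(maxsize=None)
def all_topologies(labels: frozenset) -> tuple:
    """All rooted trees (any internal out-degree >= 2) on the label set."""
    labs = sorted(labels)
    if len(labs) == 1:
        return (labs[0],)
    out = []
    for part in _set_partitions(labs):
        if len(part) < 2:
            continue
        choices = [all_topologies(frozenset(block)) for block in part]
        for combo in itertools.product(*choices):
            out.append((None, tuple(sorted(combo, key=repr))))
    return tuple(out)


def internal_slots(tree) -> int:
    if isinstance(tree, str):
        return 0
    return 1 + sum(internal_slots(c) for c in tree[1])


def label_tree(tree, bits: int, counter: list[int]):
    """Assign S/D to internal nodes from the bits of an integer, preorder."""
    if isinstance(tree, str):
        return tree
    k = counter[0]
    counter[0] += 1
    lab = "S" if bits >> k & 1 else "D"
    return (lab, tuple(label_tree(c, bits, counter) for c in tree[1]))


def all_ds_trees(labels: Iterable[str]) -> list:
    """All DS-trees (every internal node labeled S or D) on the label set."""
    out = []
    for topo in all_topologies(frozenset(labels)):
        k = internal_slots(topo)
        for bits in range(1 << k):
            out.append(label_tree(topo, bits, [0]))
    return out


def tt_leaves(tree) -> frozenset:
    if isinstance(tree, str):
        return frozenset((tree,))
    return frozenset().union(*(tt_leaves(c) for c in tree[1]))


def ortholog_pairs(tree) -> frozenset:
    """Unordered leaf pairs whose lca is labeled S."""
    pairs = set()

    def rec(t) -> list:
        if isinstance(t, str):
            return [t]
        groups = [rec(c) for c in t[1]]
        if t[0] == "S":
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for x in groups[i]:
                        for y in groups[j]:
                            pairs.add((min(x, y), max(x, y)))
        return [x for g in groups for x in g]

    rec(tree)
    return frozenset(pairs)


def clusters(tree) -> list[frozenset]:
    """Leaf cluster of every node."""
    out = []

    def rec(t) -> frozenset:
        if isinstance(t, str):
            c = frozenset((t,))
        else:
            c = frozenset().union(*(rec(ch) for ch in t[1]))
        out.append(c)
        return c

    rec(tree)
    return out


def lca_cluster(cls: list[frozenset], leaves: frozenset) -> frozenset:
    return min((c for c in cls if leaves <= c), key=len)


def tt_displays_triplet(sptree, a: str, b: str, out_label: str) -> bool:
    if out_label in (a, b):
        return False
    cls = clusters(sptree)
    inner = lca_cluster(cls, frozenset((a, b)))
    return out_label not in inner


def tt_consistent(ds_tree, sptree, species_of: dict) -> bool:
    """Definition-style consistency of a tuple DS-tree with a tuple species tree:
    every speciation node's children have pairwise disjoint species-lca clusters."""
    cls = clusters(sptree)
    ok = True

    def rec(t) -> frozenset:
        nonlocal ok
        if isinstance(t, str):
            return frozenset((species_of[t],))
        spsets = [rec(c) for c in t[1]]
        if t[0] == "S":
            lcas = [lca_cluster(cls, s) for s in spsets]
            for i in range(len(lcas)):
                for j in range(i + 1, len(lcas)):
                    if lcas[i] & lcas[j]:
                        ok = False
        return frozenset().union(*spsets)

    rec(ds_tree)
    return ok


# ---------------------------------------------------------------------------
# Exhaustive consistency oracles over small instances
# ---------------------------------------------------------------------------


def ds_trees_by_relation(labels: Sequence[str]) -> dict[frozenset, list]:
    """All DS-trees on the labels, grouped by the ortholog-pair set they induce."""
    table: dict[frozenset, list] = {}
    for t in all_ds_trees(labels):
        table.setdefault(ortholog_pairs(t), []).append(t)
    return table


def consistent_with_s_bruteforce(
    genes: Sequence[str],
    e_pairs: frozenset,
    u_pairs: frozenset,
    species_of: dict,
    sptree,
    ds_table: dict[frozenset, list],
) -> bool:
    """Exists a realization satisfied by some DS-tree consistent with the species tree."""
    u = sorted(u_pairs)
    for bits in range(1 << len(u)):
        full = set(e_pairs)
        for k, p in enumerate(u):
            if bits >> k & 1:
                full.add(p)
        for t in ds_table.get(frozenset(full), ()):
            if tt_consistent(t, sptree, species_of):
                return True
    return False


def consistent_free_bruteforce(
    genes: Sequence[str],
    e_pairs: frozenset,
    u_pairs: frozenset,
    species_of: dict,
    ds_table: dict[frozenset, list],
) -> bool:
    """Exists a species tree making the graph consistent (exhaustive tree search)."""
    species = frozenset(species_of[g] for g in genes)
    for sptree in all_topologies(species):
        if consistent_with_s_bruteforce(genes, e_pairs, u_pairs, species_of, sptree, ds_table):
            return True
    return False


def satisfiable_via_ds_trees(
    e_pairs: frozenset, u_pairs: frozenset, ds_table: dict[frozenset, list]
) -> bool:
    u = sorted(u_pairs)
    for bits in range(1 << len(u)):
        full = set(e_pairs)
        for k, p in enumerate(u):
            if bits >> k & 1:
                full.add(p)
        if frozenset(full) in ds_table:
            return True
    return False
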