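"""Random-instance generators shared across test modules (all seeded by the caller)."""

from __future__ import annotations

import itertools

import numpy as np

from orthosat import (
    ConstraintGraph,
    DSTree,
    DUP,
    FullConstraintGraph,
    GeneFamily,
    SPEC,
    SpeciesTree,
    TreeNode,
    pair,
)


def random_species_map(rng: np.random.Generator, genes, species_pool) -> dict[str, str]:
    species_pool = list(species_pool)
    return {g: species_pool[int(rng.integers(len(species_pool)))] for g in genes}


def random_family(rng: np.random.Generator, n_genes: int, n_species: int) -> GeneFamily:
    genes = [f"g{i}" for i in range(n_genes)]
    species = [f"s{i}" for i in range(n_species)]
    return GeneFamily(tuple(genes), random_species_map(rng, genes, species))


def random_bicolouring(
    rng: np.random.Generator, family: GeneFamily, p_e: float = 1 / 3, p_u: float = 1 / 3
) -> ConstraintGraph:
    """Random partial constraint graph; same-species pairs are never orthology."""
    sp = family.species_of
    e, u = set(), set()
    for p in family.pairs():
        r = rng.random()
        if r < p_e and sp[p[0]] != sp[p[1]]:
            e.add(p)
        elif r < p_e + p_u:
            u.add(p)
    return ConstraintGraph(family, frozenset(e), frozenset(u)).normalize()


def random_full_graph(
    rng: np.random.Generator, family: GeneFamily, p_e: float = 0.5
) -> FullConstraintGraph:
    sp = family.species_of
    e = {
        p
        for p in family.pairs()
        if sp[p[0]] != sp[p[1]] and rng.random() < p_e
    }
    return FullConstraintGraph(family, frozenset(e), frozenset())


def random_topology(rng: np.random.Generator, labels) -> TreeNode:
    """Random rooted tree (random out-degrees >= 2) on the given leaf labels."""
    labels = list(labels)
    if len(labels) == 1:
        return TreeNode(label=labels[0])
    k = int(rng.integers(2, min(len(labels), 4) + 1))
    perm = [labels[i] for i in rng.permutation(len(labels))]
    # split into k nonempty blocks
    cuts = sorted(rng.choice(np.arange(1, len(labels)), size=k - 1, replace=False))
    blocks, prev = [], 0
    for c in list(cuts) + [len(labels)]:
        blocks.append(perm[prev:c])
        prev = c
    return TreeNode(children=[random_topology(rng, b) for b in blocks])


def random_species_tree(rng: np.random.Generator, species) -> SpeciesTree:
    return SpeciesTree(random_topology(rng, sorted(set(species))))


def random_ds_tree(rng: np.random.Generator, genes, species_of) -> DSTree:
    """Random DS-tree respecting trivial paralogy: a speciation node never joins
    two subtrees sharing a species (such nodes are relabeled duplication)."""
    root = random_topology(rng, list(genes))

    def fix(node) -> frozenset:
        if node.is_leaf:
            return frozenset((species_of[node.label],))
        child_sets = [fix(c) for c in node.children]
        node.event = SPEC if rng.random() < 0.5 else DUP
        if node.event == SPEC:
            seen: set[str] = set()
            for cs in child_sets:
                if cs & seen:
                    node.event = DUP
                    break
                seen |= cs
        return frozenset().union(*child_sets)

    fix(root)
    return DSTree(root)


def graph_to_masks(graph: ConstraintGraph) -> tuple[int, int, list[str]]:
    """Bitmask encoding matching tests.oracles pair indexing (sorted genes)."""
    genes = sorted(graph.family.genes)
    slot = {
        (genes[i], genes[j]): k
        for k, (i, j) in enumerate(itertools.combinations(range(len(genes)), 2))
    }
    e_mask = sum(1 << slot[p] for p in graph.E)
    u_mask = sum(1 << slot[p] for p in graph.U)
    return e_mask, u_mask, genes
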