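"""Synthetic duplication/speciation histories, derived constraint graphs, and file I/O.

The generator emulates the evolution of a gene family inside a species
phylogeny: a Yule (pure-birth) species-tree topology, gene lineages that
speciate wherever their species does, duplications inserted along branches
with probability ``dup_prob`` per lineage, and losses pruning lineages with
probability ``loss_prob``.  The resulting event-labeled gene tree (a
*history*) is consistent with the generating species tree by construction;
reading off its pairwise relations yields a full constraint graph (the
*truth*), which can be degraded into a partial one by masking pairs to
unknown and, optionally, flipping known relations to fabricate
unsatisfiable/inconsistent instances.

File formats (TSV): a relations file lists ``gene1 gene2 relation`` with
relation in {orthologs, paralogs}; pairs absent from the file are unknown.
A species map file lists ``gene species``.  Note the encoding difference
from the in-memory model: on disk paralogy is explicit and unknown implicit,
in memory paralogy is implicit (non-edge) and unknown explicit (U).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .constraint_graph import ConstraintGraph, FullConstraintGraph, GeneFamily, Pair, pair
from .event_trees import (
    DSTree,
    DUP,
    SPEC,
    SpeciesTree,
    TreeNode,
    is_consistent,
    parse_newick,
)

__all__ = [
    "SimConfig",
    "SimInstance",
    "simulate",
    "simulate_species_tree",
    "read_relations",
    "write_relations",
    "read_species_map",
    "write_species_map",
    "read_species_tree",
    "write_species_tree",
    "read_ds_tree",
    "write_ds_tree",
]

_MAX_DUP_CHAIN = 4  # cap on consecutive duplications along one branch
_MAX_ATTEMPTS = 25


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated instance.

    ``n_species`` leaves in a Yule species tree; ``dup_prob`` chance of a
    duplication per gene lineage per branch (geometric chain, capped);
    ``loss_prob`` chance a lineage is pruned per branch; ``mask_frac``
    fraction of cross-species pairs moved to unknown; ``flip_frac`` fraction
    of the remaining known cross-species pairs inverted (corruption).
    """

    n_species: int = 8
    dup_prob: float = 0.2
    loss_prob: float = 0.1
    mask_frac: float = 0.25
    flip_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for name in ("dup_prob", "loss_prob", "mask_frac", "flip_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimInstance:
    """A simulated ground-truth instance: species tree, history, truth and degraded graph."""

    config: SimConfig
    species_tree: SpeciesTree
    history: DSTree
    truth: FullConstraintGraph
    graph: ConstraintGraph

    @property
    def family(self) -> GeneFamily:
        return self.truth.family


def _substream(seed: int, tag: int, attempt: int = 0) -> np.random.Generator:
    # independent stream per purpose: history stays fixed while masking varies
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag, attempt)))


def simulate_species_tree(n_species: int, rng: np.random.Generator) -> SpeciesTree:
    """Yule topology: split a uniformly chosen extant lineage until n leaves."""
    names = [f"sp{i + 1:02d}" for i in range(n_species)]
    if n_species == 1:
        return SpeciesTree(TreeNode(label=names[0]))
    root = TreeNode()
    tips = [root]
    while len(tips) < n_species:
        tip = tips.pop(int(rng.integers(len(tips))))
        left, right = TreeNode(), TreeNode()
        tip.add_child(left)
        tip.add_child(right)
        tips.extend([left, right])
    order = rng.permutation(n_species)
    for tip, k in zip(_tree_tips(root), order):
        tip.label = names[int(k)]
    return SpeciesTree(root)


def _tree_tips(root: TreeNode) -> list[TreeNode]:
    return [n for n in root.preorder() if n.is_leaf]


def _evolve(
    s_node: TreeNode,
    lineages: list[TreeNode],
    cfg: SimConfig,
    rng: np.random.Generator,
    counters: dict[str, int],
) -> None:
    """Recursively grow the gene tree along the species tree below ``s_node``."""
    if s_node.is_leaf:
        for lineage in lineages:
            counters[s_node.label] = counters.get(s_node.label, 0) + 1
            lineage.label = f"gene_{counters[s_node.label]}@{s_node.label}"
        return
    for lineage in lineages:
        lineage.event = SPEC
    for child in s_node.children:
        survivors: list[TreeNode] = []
        for lineage in lineages:
            copy = TreeNode()
            lineage.add_child(copy)
            # duplications along the branch: geometric chain, capped
            branch = [copy]
            chain = 0
            while chain < _MAX_DUP_CHAIN and rng.random() < cfg.dup_prob:
                chain += 1
                target = branch[int(rng.integers(len(branch)))]
                target.event = DUP
                a, b = TreeNode(), TreeNode()
                target.add_child(a)
                target.add_child(b)
                branch.remove(target)
                branch.extend([a, b])
            for tip in branch:
                if rng.random() < cfg.loss_prob:
                    counters["__lost__"] = counters.get("__lost__", 0) + 1
                    tip.label = f"__lost_{counters['__lost__']}__"
                else:
                    survivors.append(tip)
        _evolve(child, survivors, cfg, rng, counters)


def _relations_of(history: DSTree, family: GeneFamily) -> FullConstraintGraph:
    return FullConstraintGraph(family, history.induced_orthology(), frozenset())


def simulate(config: SimConfig) -> SimInstance:
    """Generate one instance; deterministic given ``config.seed``.

    Retries internally (bounded) when losses wipe out the family or leave a
    single gene; raises after the retry budget.
    """
    stree = simulate_species_tree(config.n_species, _substream(config.seed, 0))
    last_error: Optional[str] = None
    for attempt in range(_MAX_ATTEMPTS):
        rng_hist = _substream(config.seed, 1, attempt)
        root = TreeNode()
        counters: dict[str, int] = {}
        _evolve(stree.root, [root], config, rng_hist, counters)
        survivors = [n.label for n in root.leaves() if not n.label.startswith("__lost")]
        if not survivors or (config.n_species > 1 and len(survivors) < 2):
            last_error = "all gene lineages lost"
            continue
        full = _attach_events(root)
        history = DSTree(full).restrict(survivors)
        species_of = {g: g.split("@", 1)[1] for g in survivors}
        family = GeneFamily(tuple(sorted(survivors)), species_of)
        truth = _relations_of(history, family)
        graph = _degrade(truth, config)
        return SimInstance(
            config=config,
            species_tree=stree,
            history=history,
            truth=truth,
            graph=graph,
        )
    raise RuntimeError(f"simulation failed after {_MAX_ATTEMPTS} attempts: {last_error}")


def _attach_events(root: TreeNode) -> TreeNode:
    # unlabeled internal nodes are branch points created by duplication bookkeeping
    for node in root.preorder():
        if not node.is_leaf and node.event is None:
            node.event = DUP
    # splice out unary nodes created by single-copy branches
    def splice(node: TreeNode) -> TreeNode:
        while not node.is_leaf and len(node.children) == 1:
            node = node.children[0]
        if not node.is_leaf:
            node.children = [splice(c) for c in node.children]
            for c in node.children:
                c.parent = node
        return node

    out = splice(root)
    out.parent = None
    return out


def _degrade(truth: FullConstraintGraph, cfg: SimConfig) -> ConstraintGraph:
    cross = sorted(truth.family.cross_species_pairs())
    rng_mask = _substream(cfg.seed, 2)
    rng_flip = _substream(cfg.seed, 3)
    n_mask = int(math.floor(cfg.mask_frac * len(cross)))
    masked_idx = set(
        map(int, rng_mask.choice(len(cross), size=n_mask, replace=False))
    ) if n_mask else set()
    masked = {cross[i] for i in masked_idx}
    known = [p for p in cross if p not in masked]
    n_flip = int(math.floor(cfg.flip_frac * len(known)))
    flip_idx = set(
        map(int, rng_flip.choice(len(known), size=n_flip, replace=False))
    ) if n_flip else set()
    flipped = {known[i] for i in flip_idx}
    e = set()
    for p in cross:
        if p in masked:
            continue
        is_orth = p in truth.E
        if p in flipped:
            is_orth = not is_orth
        if is_orth:
            e.add(p)
    return ConstraintGraph(truth.family, frozenset(e), frozenset(masked))


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------

PathLike = Union[str, Path]


def read_species_map(path: PathLike) -> GeneFamily:
    species_of: dict[str, str] = {}
    order: list[str] = []
    for lineno, fields in _tsv_lines(path):
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        gene, species = fields
        if gene in species_of:
            if species_of[gene] != species:
                raise ValueError(f"{path}:{lineno}: gene {gene!r} mapped to two species")
            continue
        species_of[gene] = species
        order.append(gene)
    if not species_of:
        raise ValueError(f"{path}: empty species map")
    return GeneFamily(tuple(order), species_of)


def write_species_map(family: GeneFamily, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tspecies\n")
        for g in family.genes:
            fh.write(f"{g}\t{family.species_of[g]}\n")


def read_relations(path: PathLike, family: GeneFamily) -> ConstraintGraph:
    """Read a relations TSV against a gene family.

    Listed ``orthologs`` pairs populate E, listed ``paralogs`` pairs are
    explicit non-edges, unlisted cross-species pairs become unknown edges,
    and unlisted same-species pairs are paralogy (the mandatory trivial
    constraints).  Contradictory duplicates and unknown genes are errors.
    """
    seen: dict[Pair, str] = {}
    genes = set(family.genes)
    for lineno, fields in _tsv_lines(path):
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        g1, g2, rel = fields
        if rel not in ("orthologs", "paralogs"):
            raise ValueError(f"{path}:{lineno}: unknown relation {rel!r}")
        if g1 not in genes or g2 not in genes:
            missing = g1 if g1 not in genes else g2
            raise ValueError(f"{path}:{lineno}: gene {missing!r} absent from species map")
        if g1 == g2:
            raise ValueError(f"{path}:{lineno}: self-pair {g1!r}")
        p = pair(g1, g2)
        if p in seen and seen[p] != rel:
            raise ValueError(f"{path}:{lineno}: contradictory duplicate for pair {p}")
        seen[p] = rel
    e = frozenset(p for p, rel in seen.items() if rel == "orthologs")
    u = frozenset(
        p for p in family.cross_species_pairs() if p not in seen
    )
    return ConstraintGraph(family, e, u).normalize()


def write_relations(graph: ConstraintGraph, path: PathLike) -> None:
    """Write orthology edges and cross-species paralogy non-edges; unknowns are implicit."""
    sp = graph.family.species_of
    lines = []
    for p in sorted(graph.E):
        lines.append((p[0], p[1], "orthologs"))
    for p in sorted(graph.non_edges()):
        if sp[p[0]] != sp[p[1]]:
            lines.append((p[0], p[1], "paralogs"))
    with open(path, "w") as fh:
        fh.write("#gene1\tgene2\trelation\n")
        for row in lines:
            fh.write("\t".join(row) + "\n")


def _tsv_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_species_tree(path: PathLike) -> SpeciesTree:
    text = Path(path).read_text()
    return SpeciesTree(parse_newick(text))


def write_species_tree(tree: SpeciesTree, path: PathLike) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_ds_tree(path: PathLike) -> DSTree:
    text = Path(path).read_text()
    return DSTree(parse_newick(text, with_events=True))


def write_ds_tree(tree: DSTree, path: PathLike, dialect: str = "label") -> None:
    """``dialect="label"`` writes S/D internal labels; ``"nhx"`` writes NHX Ev comments."""
    if dialect not in ("label", "nhx"):
        raise ValueError("dialect must be 'label' or 'nhx'")
    Path(path).write_text(tree.newick(events=dialect) + "\n")
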