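"""Heuristic search for optimal trees under parsimony length or
implied-weighting distortion, with converse-constraint variants used for
decay indices.

Searches operate on binary trees held rooted at a designated base taxon;
scores are rooting-invariant, so this is an unrooted search with a fixed
display rooting.  The replicate protocol is seeded random stepwise
addition followed by branch swapping to closure over the island of
equally optimal trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .matrix_io import CharacterMatrix, CharacterSettings
from .parsimony import TreeScorer
from .tree import Node, Tree, TreeError

__all__ = [
    "SearchConfig", "Constraint", "TreeSet", "random_addition_tree",
    "swap_to_optimum", "search_battery", "constrained_search",
    "enumerate_unrooted_trees", "exhaustive_search", "has_clade",
]

SCORE_TOL = 1e-8
_PENALTY = 1e9


@dataclass
class Constraint:
    clade: frozenset
    mode: str = "FORBID"  # or "ENFORCE"

    def __post_init__(self):
        self.clade = frozenset(self.clade)
        if self.mode not in ("FORBID", "ENFORCE"):
            raise ValueError(f"unknown constraint mode {self.mode!r}")


@dataclass
class SearchConfig:
    n_replicates: int = 100
    seed: int = 0
    swap: str = "SPR"                  # "SPR" or "TBR"
    max_saved_trees: int = 10_000
    collapse_rule: str = "MIN_LENGTH_ZERO"  # or "NONE"
    constraint: Optional[Constraint] = None
    root_taxon: Optional[str] = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_saved_trees < 1:
            raise ValueError("max_saved_trees must be >= 1")
        if self.swap not in ("SPR", "TBR"):
            raise ValueError(f"unknown swap {self.swap!r}")


@dataclass
class TreeSet:
    trees: list
    best_score: float
    provenance: list = field(default_factory=list)  # (replicate id, score)
    truncated: bool = False

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ------------------------------------------------------------- topology ops
def has_clade(tree: Tree, clade: frozenset) -> bool:
    """Is ``clade`` monophyletic once the tree is rooted outside it?

    Checked unrooted: the clade (or its leaf-set complement) must appear
    as a node leaf set, so the answer does not depend on where the search
    happens to display the root.  The caller guarantees the designated
    root taxon is outside ``clade``."""
    clade = frozenset(clade)
    comp = tree.leaf_labels() - clade
    clades = tree.clades()
    return clade in clades or comp in clades


def _satisfies(tree: Tree, constraint: Optional[Constraint]) -> bool:
    if constraint is None:
        return True
    present = has_clade(tree, constraint.clade)
    return (not present) if constraint.mode == "FORBID" else present


def _base_root(taxa: list[str], root_taxon: Optional[str]) -> str:
    if root_taxon is None:
        return taxa[0]
    if root_taxon not in taxa:
        raise TreeError(f"root taxon {root_taxon!r} not in matrix")
    return root_taxon


def _three_taxon_tree(base: str, t1: str, t2: str) -> Tree:
    root = Node()
    root.add_child(Node(base))
    inner = root.add_child(Node())
    inner.add_child(Node(t1))
    inner.add_child(Node(t2))
    return Tree(root)


def _attachment_points(tree: Tree) -> list[Node]:
    """Nodes above which a new leaf may be inserted.  The branches above
    the two root children are the same unrooted edge, so only one of the
    pair is offered."""
    first = tree.root.children[0]
    return [nd for nd in tree.postorder()
            if nd.parent is not None and nd is not first]


def _insert_leaf_above(tree: Tree, node: Node, label: str) -> Node:
    """Insert a new leaf on the branch above ``node``; returns the new leaf."""
    parent = node.parent
    idx = parent.children.index(node)
    joint = Node()
    parent.children[idx] = joint
    joint.parent = parent
    joint.add_child(node)
    leaf = joint.add_child(Node(label))
    return leaf


def _remove_leaf(tree: Tree, leaf: Node) -> None:
    joint = leaf.parent
    joint.children.remove(leaf)
    tree.suppress_unifurcations(keep_sampled_ancestors=False)


def _prunable(nd: Node, root: Node) -> bool:
    # root children stay put: moving the whole non-base side is a no-op
    return nd.parent is not None and nd.parent is not root


def _detach_subtree(tree: Tree, node: Node) -> None:
    parent = node.parent
    node.detach()
    if parent is not None and len(parent.children) == 1:
        only = parent.children[0]
        if parent.parent is None:
            # never happens: base child is not prunable
            only.parent = None
            tree.root = only
        else:
            gp = parent.parent
            idx = gp.children.index(parent)
            gp.children[idx] = only
            only.parent = gp


def _regraft_above(tree: Tree, target: Node, subtree: Node) -> None:
    parent = target.parent
    idx = parent.children.index(target)
    joint = Node()
    parent.children[idx] = joint
    joint.parent = parent
    joint.add_child(target)
    joint.add_child(subtree)


def _subtree_rerootings(node: Node) -> list[Node]:
    """All re-anchorings of an unrooted reading of ``subtree(node)``.

    Returns fresh copies; the original is left untouched.  Each result is a
    node whose two children partition the subtree's leaves, anchored at one
    of its internal edges (TBR reconnection points)."""
    base = Tree(_clone(node))
    out = [base.root]
    internal_edges = [nd for nd in base.root.postorder()
                      if nd.parent is not None and nd.parent is not base.root]
    for anchor in internal_edges:
        t2 = Tree(_clone(base.root))
        # find corresponding node by path
        path = _path_from_root(base.root, anchor)
        target = t2.root
        for i in path:
            target = target.children[i]
        out.append(_reanchor(t2, target))
    return out


def _path_from_root(root: Node, node: Node) -> list[int]:
    path = []
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return list(reversed(path))


def _clone(node: Node) -> Node:
    c = Node(node.label, node.length)
    for ch in node.children:
        c.add_child(_clone(ch))
    return c


def _reanchor(tree: Tree, edge_child: Node) -> Node:
    """Re-anchor the unrooted reading of ``tree`` at the edge above
    ``edge_child``; returns the new binary anchor node."""
    # invert parent pointers from edge_child's parent up to the old root
    chain = []
    nd = edge_child.parent
    while nd is not None:
        chain.append(nd)
        nd = nd.parent
    edge_child.detach()
    new_root = Node()
    new_root.add_child(edge_child)
    prev = new_root
    for i, nd in enumerate(chain):
        parent = chain[i + 1] if i + 1 < len(chain) else None
        if parent is not None:
            parent.children.remove(nd)
        nd.parent = None
        prev.add_child(nd)
        prev = nd
    # suppress unifurcations created along the inverted chain
    t = Tree(new_root)
    t.suppress_unifurcations(keep_sampled_ancestors=False)
    return t.root


# ----------------------------------------------------------------- moves
def spr_neighbors(tree: Tree) -> Iterator[Tree]:
    n_nodes = sum(1 for _ in tree.postorder())
    for i in range(n_nodes):
        work = tree.copy()
        nodes = list(work.postorder())
        sub = nodes[i]
        if not _prunable(sub, work.root):
            continue
        _detach_subtree(work, sub)
        for target in list(work.postorder()):
            if target.parent is None:
                continue
            cand = work.copy()
            cmap = dict(zip(map(id, work.postorder()), cand.postorder()))
            _regraft_above(cand, cmap[id(target)], _clone(sub))
            yield cand


def tbr_neighbors(tree: Tree) -> Iterator[Tree]:
    n_nodes = sum(1 for _ in tree.postorder())
    for i in range(n_nodes):
        work = tree.copy()
        nodes = list(work.postorder())
        sub = nodes[i]
        if not _prunable(sub, work.root):
            continue
        _detach_subtree(work, sub)
        for anchored in _subtree_rerootings(sub):
            for target in list(work.postorder()):
                if target.parent is None:
                    continue
                cand = work.copy()
                cmap = dict(zip(map(id, work.postorder()), cand.postorder()))
                _regraft_above(cand, cmap[id(target)], _clone(anchored))
                yield cand


# ------------------------------------------------------------ components
def random_addition_tree(matrix: CharacterMatrix,
                         settings: Optional[CharacterSettings] = None,
                         seed: int = 0,
                         root_taxon: Optional[str] = None,
                         scorer: Optional[TreeScorer] = None) -> Tree:
    """Stepwise addition: taxa inserted in seeded random order at the
    locally optimal attachment point."""
    if matrix.n_taxa < 3:
        raise TreeError("need at least 3 taxa")
    scorer = scorer or TreeScorer(matrix, settings)
    rng = np.random.default_rng(seed)
    base = _base_root(matrix.taxa, root_taxon)
    others = [t for t in matrix.taxa if t != base]
    order = [others[i] for i in rng.permutation(len(others))]
    tree = _three_taxon_tree(base, order[0], order[1])
    for label in order[2:]:
        best_nodes, best_score = [], None
        for node in _attachment_points(tree):
            leaf = _insert_leaf_above(tree, node, label)
            s = scorer.objective(tree)
            _remove_leaf(tree, leaf)
            if best_score is None or s < best_score - SCORE_TOL:
                best_score, best_nodes = s, [node]
            elif s <= best_score + SCORE_TOL:
                best_nodes.append(node)
        choice = best_nodes[rng.integers(len(best_nodes))]
        _insert_leaf_above(tree, choice, label)
    return tree


def _scored(tree: Tree, scorer: TreeScorer,
            constraint: Optional[Constraint]) -> float:
    s = scorer.objective(tree)
    if not _satisfies(tree, constraint):
        s += _PENALTY
    return s


def swap_to_optimum(start: Tree, matrix: CharacterMatrix,
                    settings: Optional[CharacterSettings] = None,
                    config: Optional[SearchConfig] = None,
                    scorer: Optional[TreeScorer] = None) -> TreeSet:
    """Greedy SPR/TBR descent keeping all equally optimal topologies in
    the island reachable through optimal intermediates."""
    config = config or SearchConfig()
    scorer = scorer or TreeScorer(matrix, settings)
    neighbor_fn = tbr_neighbors if config.swap == "TBR" else spr_neighbors

    best = _scored(start, scorer, config.constraint)
    keys = {_topo_key(start)}
    pool = [start.copy()]
    frontier = [start.copy()]
    truncated = False
    while frontier:
        current = frontier.pop()
        for nb in neighbor_fn(current):
            s = _scored(nb, scorer, config.constraint)
            if s < best - SCORE_TOL:
                best = s
                keys = {_topo_key(nb)}
                pool = [nb]
                frontier = [nb]
                truncated = False
                break
            if s <= best + SCORE_TOL:
                k = _topo_key(nb)
                if k not in keys:
                    if len(pool) >= config.max_saved_trees:
                        truncated = True
                        continue
                    keys.add(k)
                    pool.append(nb)
                    frontier.append(nb)
        else:
            continue
    return TreeSet(trees=pool, best_score=best, truncated=truncated)


def _topo_key(tree: Tree) -> frozenset:
    return frozenset(tree.bipartitions())


def search_battery(matrix: CharacterMatrix,
                   settings: Optional[CharacterSettings] = None,
                   config: Optional[SearchConfig] = None) -> TreeSet:
    """Replicated random-addition + swapping, pooling all trees at the
    global best score, then re-swapping from every pooled tree."""
    config = config or SearchConfig()
    scorer = TreeScorer(matrix, settings)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    best: Optional[float] = None
    pooled: list[Tree] = []
    keys: set = set()
    provenance = []
    truncated = False
    for rep, ss in enumerate(seeds):
        rep_seed = int(ss.generate_state(1)[0])
        start = random_addition_tree(matrix, settings, seed=rep_seed,
                                     root_taxon=config.root_taxon, scorer=scorer)
        result = swap_to_optimum(start, matrix, settings, config, scorer=scorer)
        truncated = truncated or result.truncated
        if best is None or result.best_score < best - SCORE_TOL:
            best = result.best_score
            pooled, keys, provenance = [], set(), []
        if result.best_score <= best + SCORE_TOL:
            for t in result.trees:
                k = _topo_key(t)
                if k not in keys:
                    keys.add(k)
                    pooled.append(t)
                    provenance.append((rep, result.best_score))
    # closure: re-swap from every pooled tree until no new optimum appears
    changed = True
    while changed:
        changed = False
        for t in list(pooled):
            result = swap_to_optimum(t, matrix, settings, config, scorer=scorer)
            truncated = truncated or result.truncated
            if result.best_score < best - SCORE_TOL:
                best = result.best_score
                pooled, keys, provenance = [], set(), []
            for nt in result.trees:
                if result.best_score <= best + SCORE_TOL:
                    k = _topo_key(nt)
                    if k not in keys:
                        if len(pooled) >= config.max_saved_trees:
                            truncated = True
                            continue
                        keys.add(k)
                        pooled.append(nt)
                        provenance.append((-1, result.best_score))
                        changed = True
    final = _finalize(pooled, scorer, config)
    return TreeSet(trees=final, best_score=best, provenance=provenance,
                   truncated=truncated)


def _finalize(trees: list[Tree], scorer: TreeScorer,
              config: SearchConfig) -> list[Tree]:
    """Apply the collapse rule, deduplicate, and sort canonically."""
    out, seen = [], set()
    for t in trees:
        c = t.copy()
        if config.collapse_rule == "MIN_LENGTH_ZERO":
            for nd in scorer.zero_min_length_branches(c):
                c.collapse_branch(nd)
        k = _topo_key(c)
        if k not in seen:
            seen.add(k)
            c.ladderize()
            out.append(c)
    out.sort(key=lambda t: t.to_newick(with_lengths=False))
    return out


def constrained_search(matrix: CharacterMatrix,
                       settings: Optional[CharacterSettings],
                       config: SearchConfig) -> TreeSet:
    """Search restricted to trees violating (FORBID) or containing
    (ENFORCE) a clade; used for decay indices."""
    if config.constraint is None:
        raise ValueError("constrained_search needs a constraint")
    unknown = config.constraint.clade - set(matrix.taxa)
    if unknown:
        raise TreeError(f"constraint names unknown taxa: {sorted(unknown)}")
    if not (0 < len(config.constraint.clade) < matrix.n_taxa):
        raise ValueError("constraint clade must be a proper subset of taxa")
    result = search_battery(matrix, settings, config)
    if result.best_score >= _PENALTY / 2:
        raise TreeError("no tree satisfying the constraint was found")
    return result


# -------------------------------------------------------------- exhaustive
def enumerate_unrooted_trees(taxa: list[str]) -> Iterator[Tree]:
    """All unrooted binary topologies, displayed rooted at taxa[0].

    1, 1, 3, 15, 105, 945 trees for 3..8 taxa."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def build(tree: Tree, remaining: list[str]) -> Iterator[Tree]:
        if not remaining:
            yield tree.copy()
            return
        label, rest = remaining[0], remaining[1:]
        points = _attachment_points(tree)
        for node in points:
            leaf = _insert_leaf_above(tree, node, label)
            yield from build(tree, rest)
            _remove_leaf(tree, leaf)

    start = _three_taxon_tree(taxa[0], taxa[1], taxa[2])
    yield from build(start, list(taxa[3:]))


def exhaustive_search(matrix: CharacterMatrix,
                      settings: Optional[CharacterSettings] = None,
                      constraint: Optional[Constraint] = None,
                      root_taxon: Optional[str] = None) -> TreeSet:
    """Brute-force optimum over all unrooted topologies (small n only)."""
    scorer = TreeScorer(matrix, settings)
    base = _base_root(matrix.taxa, root_taxon)
    taxa = [base] + [t for t in matrix.taxa if t != base]
    best, pool = None, []
    for t in enumerate_unrooted_trees(taxa):
        if not _satisfies(t, constraint):
            continue
        s = scorer.objective(t)
        if best is None or s < best - SCORE_TOL:
            best, pool = s, [t.copy()]
        elif s <= best + SCORE_TOL:
            pool.append(t.copy())
    if best is None:
        raise TreeError("no tree satisfies the constraint")
    return TreeSet(trees=pool, best_score=best)
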