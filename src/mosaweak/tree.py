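"""Rooted phylogenetic trees with optional branch durations, node ages,
and sampled-ancestor marks.

Trees are rooted; unrooted semantics (parsimony scoring, bipartition
comparison) are obtained by ignoring the root placement.  Sampled
ancestors are degree-2 sample points on a branch; on serialization they
become zero-length leaf attachments (see :meth:`Tree.to_newick`).
"""

from __future__ import annotations

import io
from typing import Callable, Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "TreeError"]

#: leaf branch lengths at or below this are read back as sampled ancestors
SA_LENGTH_TOL = 1e-12


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("children", "parent", "label", "length", "age", "sampled_ancestor")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.label = label
        self.length = length
        self.age: Optional[float] = None
        self.sampled_ancestor = False

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list["Node"]:
        return [nd for nd in self.postorder() if nd.is_leaf()]

    def leaf_labels(self) -> frozenset:
        """Labels of all samples: terminal leaves plus sampled ancestors,
        so the label set is invariant to SA <-> terminal toggling."""
        return frozenset(nd.label for nd in self.postorder()
                         if nd.is_leaf() or nd.sampled_ancestor)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '·'} nchild={len(self.children)}>"


class Tree:
    """A rooted tree; exactly one root node."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walks
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset:
        return self.root.leaf_labels()

    def find_leaf(self, label: str) -> Node:
        for nd in self.leaves():
            if nd.label == label:
                return nd
        raise TreeError(f"leaf {label!r} not in tree")

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def copy(self) -> "Tree":
        def clone(nd: Node) -> Node:
            c = Node(nd.label, nd.length)
            c.age = nd.age
            c.sampled_ancestor = nd.sampled_ancestor
            for ch in nd.children:
                c.add_child(clone(ch))
            return c

        return Tree(clone(self.root))

    # --------------------------------------------------------------- topology
    def clades(self) -> set[frozenset]:
        """Label sets of every internal node (rooted clades), root included;
        sampled ancestors are counted as members of their own clade."""
        labels = self.node_leafsets()
        return {labels[id(nd)] for nd in self.postorder() if not nd.is_leaf()}

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each encoded as the side NOT
        containing the alphabetically first leaf label."""
        all_labels = self.leaf_labels()
        ref = min(all_labels)
        out = set()
        for clade in self.clades():
            side = clade if ref not in clade else all_labels - clade
            if 1 < len(side) < len(all_labels) - 1:
                out.add(side)
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        missing = want - set(self.leaf_labels())
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        counts: dict[int, int] = {}
        target = len(want)
        for nd in self.postorder():
            own = 1 if ((nd.is_leaf() or nd.sampled_ancestor)
                        and nd.label in want) else 0
            counts[id(nd)] = own + sum(counts[id(c)] for c in nd.children)
            if counts[id(nd)] == target:
                return nd
        raise TreeError("mrca not found")  # pragma: no cover

    def node_leafsets(self) -> dict[int, frozenset]:
        out: dict[int, frozenset] = {}
        for nd in self.postorder():
            s = frozenset().union(*(out[id(c)] for c in nd.children)) \
                if nd.children else frozenset()
            if nd.is_leaf() or nd.sampled_ancestor:
                s = s | frozenset([nd.label])
            out[id(nd)] = s
        return out

    def is_binary(self) -> bool:
        return all(len(nd.children) in (0, 2) for nd in self.postorder()
                   if not nd.is_leaf())

    # ---------------------------------------------------------------- ages
    def set_ages_from_lengths(self, tip_ages: Optional[dict] = None) -> None:
        """Assign node ages from branch durations.  With no tip ages all
        leaves are placed at age 0 (ultrametric reading is not assumed:
        ages come from the root-to-node path)."""
        depth = {id(self.root): 0.0}
        maxdepth = 0.0
        for nd in self.preorder():
            if nd.parent is not None:
                depth[id(nd)] = depth[id(nd.parent)] + (nd.length or 0.0)
                maxdepth = max(maxdepth, depth[id(nd)])
        if tip_ages:
            some = next(iter(self.leaves()))
            root_age = tip_ages[some.label] + depth[id(some)]
        else:
            root_age = maxdepth
        for nd in self.preorder():
            nd.age = root_age - depth[id(nd)]

    def set_lengths_from_ages(self) -> None:
        for nd in self.preorder():
            if nd.parent is not None:
                nd.length = nd.parent.age - nd.age

    def check_ages(self, tol: float = 1e-9) -> None:
        for nd in self.preorder():
            if nd.parent is not None and nd.age is not None:
                if nd.age > nd.parent.age + tol:
                    raise TreeError(
                        f"node age {nd.age} exceeds parent age {nd.parent.age}")

    # ------------------------------------------------------------- transforms
    def collapse_branch(self, node: Node) -> None:
        """Collapse the branch above ``node`` (merge node into its parent)."""
        parent = node.parent
        if parent is None or node.is_leaf():
            raise TreeError("can only collapse internal, non-root branches")
        idx = parent.children.index(node)
        parent.children.pop(idx)
        for i, ch in enumerate(node.children):
            ch.parent = parent
            parent.children.insert(idx + i, ch)

    def suppress_unifurcations(self, keep_sampled_ancestors: bool = True) -> None:
        changed = True
        while changed:
            changed = False
            for nd in list(self.preorder()):
                if nd.is_leaf() or len(nd.children) != 1:
                    continue
                if keep_sampled_ancestors and nd.sampled_ancestor:
                    continue
                child = nd.children[0]
                if nd.parent is None:
                    child.parent = None
                    if nd.length is not None and child.length is not None:
                        child.length += nd.length
                    self.root = child
                else:
                    p = nd.parent
                    idx = p.children.index(nd)
                    p.children[idx] = child
                    child.parent = p
                    if nd.length is not None and child.length is not None:
                        child.length += nd.length
                changed = True
                break

    def canonical_key(self) -> tuple:
        """Order-invariant structural key (topology + labels only)."""

        def key(nd: Node):
            if nd.is_leaf():
                return (0, nd.label)
            return (1, tuple(sorted(key(c) for c in nd.children)))

        return key(self.root)

    def ladderize(self) -> None:
        for nd in self.postorder():
            if not nd.is_leaf():
                nd.children.sort(key=lambda c: (len(c.leaf_labels()),
                                                min(c.leaf_labels())))

    # --------------------------------------------------------------------- IO
    def to_newick(self, with_lengths: bool = True, precision: int = 10) -> str:
        for leaf in self.leaves():
            if leaf.label is None:
                raise TreeError("unlabeled leaf cannot be serialized")

        def fmt(nd: Node) -> str:
            if nd.is_leaf():
                s = _quote(nd.label)
            elif len(nd.children) == 1 and nd.sampled_ancestor:
                # degree-2 sampled ancestor -> zero-length leaf attachment
                inner = fmt(nd.children[0])
                sa = _quote(nd.label) + (":0.0" if with_lengths else "")
                s = f"({inner},{sa})"
            else:
                s = "(" + ",".join(fmt(c) for c in nd.children) + ")"
                if nd.label and not nd.is_leaf():
                    s += _quote(nd.label)
            if with_lengths and nd.length is not None and nd.parent is not None:
                s += f":{nd.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=False)
        root = _from_dendropy(dt.seed_node)
        tree = cls(root)
        _restore_sampled_ancestors(tree)
        return tree

    def __repr__(self):  # pragma: no cover
        return f"<Tree n_leaves={self.n_leaves()}>"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    nd = Node(label, dnode.edge.length)
    for ch in dnode.child_nodes():
        nd.add_child(_from_dendropy(ch))
    return nd


def _restore_sampled_ancestors(tree: Tree) -> None:
    """Fold zero-length leaf attachments back into degree-2 SA nodes."""
    changed = True
    while changed:
        changed = False
        for nd in list(tree.preorder()):
            if nd.is_leaf() or len(nd.children) != 2:
                continue
            for ch in nd.children:
                if (ch.is_leaf() and ch.length is not None
                        and abs(ch.length) <= SA_LENGTH_TOL):
                    other = nd.children[0] if ch is nd.children[1] else nd.children[1]
                    nd.label = ch.label
                    nd.sampled_ancestor = True
                    nd.children = [other]
                    other.parent = nd
                    changed = True
                    break
            if changed:
                break


# ----------------------------------------------------------------- NEXUS IO
def write_nexus_trees(trees: list[Tree], path, names: Optional[list[str]] = None,
                      with_lengths: bool = True) -> None:
    names = names or [f"tree_{i+1}" for i in range(len(trees))]
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin trees;\n")
        for name, t in zip(names, trees):
            fh.write(f"  tree {name} = {t.to_newick(with_lengths=with_lengths)}\n")
        fh.write("end;\n")


def read_nexus_trees(path) -> list[Tree]:
    tl = dendropy.TreeList.get(path=str(path), schema="nexus",
                               preserve_underscores=True)
    out = []
    for dt in tl:
        tree = Tree(_from_dendropy(dt.seed_node))
        _restore_sampled_ancestors(tree)
        out.append(tree)
    return out
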