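"""Consensus trees, Bremer decay indices, and nonparametric bootstrap
proportions over tree sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .matrix_io import CharacterMatrix, CharacterSettings
from .search import (Constraint, SearchConfig, TreeSet, constrained_search,
                     search_battery)
from .tree import Node, Tree, TreeError

__all__ = [
    "SupportReport", "strict_consensus", "majority_consensus",
    "bremer_support", "bootstrap", "clade_frequencies",
]


@dataclass
class CladeSupport:
    taxa: frozenset
    bremer: Optional[float] = None
    bremer_censored: bool = False      # True -> value is a lower bound (">X")
    bootstrap: Optional[float] = None
    present_in_strict: bool = False
    n_reps: Optional[int] = None

    def bremer_str(self) -> str:
        if self.bremer is None:
            return ""
        v = int(self.bremer) if float(self.bremer).is_integer() else self.bremer
        return f">{v}" if self.bremer_censored else f"{v}"


@dataclass
class SupportReport:
    clades: dict = field(default_factory=dict)  # frozenset -> CladeSupport

    def get(self, taxa) -> Optional[CladeSupport]:
        return self.clades.get(frozenset(taxa))

    def add(self, sup: CladeSupport) -> None:
        self.clades[sup.taxa] = sup


# -------------------------------------------------------------- consensus
def _check_leafsets(trees: Sequence[Tree]) -> frozenset:
    if not trees:
        raise TreeError("need at least one tree")
    labels = trees[0].leaf_labels()
    for t in trees[1:]:
        if t.leaf_labels() != labels:
            raise TreeError("trees have mismatched leaf sets")
    return labels


def _consensus_from_clades(labels: frozenset, clades: list[frozenset],
                           freqs: Optional[dict] = None) -> Tree:
    """Build a rooted tree from a set of mutually compatible clades."""
    clades = sorted(set(clades), key=len, reverse=True)
    root = Node()
    root.age = None
    node_of: dict[frozenset, Node] = {labels: root}
    # attach clades from largest to smallest under the smallest enclosing one
    for clade in clades:
        if clade == labels:
            continue
        enclosing = min((c for c in node_of if clade < c), key=len)
        nd = node_of[enclosing].add_child(Node())
        if freqs is not None:
            nd.label = f"{freqs[clade]:.3f}"
        node_of[clade] = nd
    for leaf in sorted(labels):
        enclosing = min((c for c in node_of if leaf in c), key=len)
        node_of[enclosing].add_child(Node(leaf))
    tree = Tree(root)
    tree.ladderize()
    return tree


def clade_frequencies(trees: Sequence[Tree]) -> dict:
    """Rooted-clade frequency across trees (proportions)."""
    labels = _check_leafsets(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for clade in t.clades():
            if 1 < len(clade) < len(labels):
                counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return {c: k / n for c, k in counts.items()}


def strict_consensus(trees: Sequence[Tree] | TreeSet) -> Tree:
    trees = list(trees)
    labels = _check_leafsets(trees)
    freqs = clade_frequencies(trees)
    keep = [c for c, f in freqs.items() if f == 1.0]
    return _consensus_from_clades(labels, keep)


def majority_consensus(trees: Sequence[Tree] | TreeSet,
                       cutoff: float = 0.5) -> Tree:
    """Clades with frequency > cutoff; frequencies annotated on labels."""
    if cutoff < 0.5:
        raise ValueError("cutoff must be >= 0.5 for a compatible consensus")
    trees = list(trees)
    labels = _check_leafsets(trees)
    freqs = clade_frequencies(trees)
    keep = [c for c, f in freqs.items() if f > cutoff]
    return _consensus_from_clades(labels, keep, freqs=freqs)


# ----------------------------------------------------------------- bremer
def bremer_support(matrix: CharacterMatrix,
                   settings: Optional[CharacterSettings],
                   optima: TreeSet,
                   clades: Optional[Sequence[frozenset]] = None,
                   config: Optional[SearchConfig] = None) -> SupportReport:
    """Decay index per clade: extra steps of the best tree lacking it.

    ``clades`` defaults to the internal clades of the strict consensus of
    the optima (excluding the root-adjacent trivial clade)."""
    config = config or SearchConfig(n_replicates=10)
    consensus = strict_consensus(list(optima))
    labels = consensus.leaf_labels()
    if clades is None:
        clades = sorted((c for c in consensus.clades()
                         if 1 < len(c) < len(labels) - 1),
                        key=lambda c: (len(c), sorted(c)))
    report = SupportReport()
    strict_clades = consensus.clades()
    for clade in clades:
        clade = frozenset(clade)
        in_strict = clade in strict_clades
        present_somewhere = any(clade in t.clades() for t in optima)
        if not present_somewhere:
            report.add(CladeSupport(taxa=clade, bremer=0.0,
                                    present_in_strict=in_strict))
            continue
        ccfg = SearchConfig(
            n_replicates=config.n_replicates, seed=config.seed,
            swap=config.swap, max_saved_trees=config.max_saved_trees,
            collapse_rule=config.collapse_rule,
            constraint=Constraint(clade=clade, mode="FORBID"),
            root_taxon=config.root_taxon)
        constrained = constrained_search(matrix, settings, ccfg)
        di = constrained.best_score - optima.best_score
        report.add(CladeSupport(taxa=clade, bremer=di,
                                bremer_censored=constrained.truncated,
                                present_in_strict=in_strict))
    return report


# -------------------------------------------------------------- bootstrap
def bootstrap(matrix: CharacterMatrix,
              settings: Optional[CharacterSettings] = None,
              config: Optional[SearchConfig] = None,
              n_reps: int = 500,
              seed: int = 0,
              clades: Optional[Sequence[frozenset]] = None) -> SupportReport:
    """Character bootstrap: clade frequency = fraction of replicates whose
    strict consensus of best trees contains the clade."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or SearchConfig(n_replicates=10)
    rng = np.random.default_rng(seed)
    active = matrix.active_indices()
    counts: dict[frozenset, int] = {}
    track = None if clades is None else [frozenset(c) for c in clades]
    for rep in range(n_reps):
        picks = [active[i] for i in rng.integers(len(active), size=len(active))]
        bmat = matrix.resample_characters(picks)
        rep_cfg = SearchConfig(
            n_replicates=config.n_replicates,
            seed=int(rng.integers(2 ** 31)),
            swap=config.swap, max_saved_trees=config.max_saved_trees,
            collapse_rule=config.collapse_rule, root_taxon=config.root_taxon)
        result = search_battery(bmat, settings, rep_cfg)
        found = strict_consensus(list(result)).clades()
        for clade in found:
            counts[clade] = counts.get(clade, 0) + 1
    report = SupportReport()
    keys = track if track is not None else sorted(counts, key=sorted)
    for clade in keys:
        report.add(CladeSupport(taxa=clade,
                                bootstrap=counts.get(clade, 0) / n_reps,
                                n_reps=n_reps))
    return report
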