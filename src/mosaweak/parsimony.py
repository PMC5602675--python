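"""Parsimony scoring: Fitch (unordered) and additive (ordered) step
counts, per-character step bounds, ensemble indices, and implied-weighting
distortion.

Two scoring routes are kept deliberately distinct: a generalized Sankoff
dynamic program (exact for any node degree, any linear cost), and a
bit-parallel Fitch pass used as the fast path for binary trees with
unordered characters.  The Sankoff route doubles as the reference scorer
in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .matrix_io import CharacterMatrix, CharacterSettings
from .tree import Tree, TreeError

__all__ = [
    "ScoreBreakdown", "TreeScorer", "char_steps", "tree_length",
    "ensemble_indices", "iw_score", "min_steps", "max_steps",
    "zero_min_length_branches", "RIUndefinedError",
]

INF = np.int64(1 << 40)


class RIUndefinedError(ValueError):
    """No character has any potential homoplasy (sum max == sum min)."""


@dataclass
class ScoreBreakdown:
    total_length: float
    per_char_steps: np.ndarray     # active characters, matrix order
    per_char_min: np.ndarray
    per_char_max: np.ndarray
    char_indices: np.ndarray       # 0-based indices of the active characters
    weights: np.ndarray

    @property
    def homoplasy(self) -> np.ndarray:
        return self.per_char_steps - self.per_char_min

    def iw_distortion(self, K: float) -> float:
        h = self.homoplasy.astype(float)
        return float(np.sum(h / (h + K)))


# ----------------------------------------------------------- step bounds
def min_steps(column: list[frozenset], state_count: int, ordered: bool) -> int:
    """Minimum steps attainable for this character on *any* tree."""
    sets = [s for s in column if len(s) < state_count]
    if not sets:
        return 0
    if ordered:
        lo = max(min(s) for s in sets)
        hi = min(max(s) for s in sets)
        return max(0, lo - hi)
    # unordered: smallest set of states hitting every cell, minus one
    distinct = set(sets)
    states = sorted(set().union(*distinct))
    for size in range(1, len(states) + 1):
        for combo in combinations(states, size):
            cs = set(combo)
            if all(cs & s for s in distinct):
                return size - 1
    return len(states) - 1  # pragma: no cover


def max_steps(column: list[frozenset], state_count: int, ordered: bool) -> int:
    """Steps on the star tree (ambiguity resolved minimally), the RI bound."""
    sets = [s for s in column if len(s) < state_count]
    if not sets:
        return 0
    if not ordered:
        best = max(sum(1 for s in sets if c in s) for c in range(state_count))
        return len(sets) - best
    return min(sum(min(abs(x - c) for x in s) for s in sets)
               for c in range(state_count))


# --------------------------------------------------------------- scorer
class TreeScorer:
    """Scores trees against a fixed (matrix, settings) pair.

    Encodes unordered characters as bitmasks for a vectorized Fitch pass
    on binary trees; everything else goes through vectorized Sankoff.
    """

    def __init__(self, matrix: CharacterMatrix, settings: Optional[CharacterSettings] = None):
        settings = settings or CharacterSettings()
        settings.validate(matrix.n_char)
        self.matrix = matrix
        self.settings = settings
        self.taxon_index = {t: i for i, t in enumerate(matrix.taxa)}

        active = matrix.active_indices()
        self.active = np.array(active, dtype=np.int64)
        self.weights = np.array([matrix.weight[j] for j in active])
        ordered_flags = [settings.is_ordered(j) for j in active]

        self._mins = np.array([
            min_steps(matrix.column(j), matrix.state_count[j], o)
            for j, o in zip(active, ordered_flags)], dtype=np.int64)
        self._maxs = np.array([
            max_steps(matrix.column(j), matrix.state_count[j], o)
            for j, o in zip(active, ordered_flags)], dtype=np.int64)

        # unordered characters: bitmask encoding (state_count <= 32)
        self.unord_pos = [p for p, o in enumerate(ordered_flags) if not o]
        self.ord_pos = [p for p, o in enumerate(ordered_flags) if o]
        uj = [active[p] for p in self.unord_pos]
        self._fitch_masks = np.zeros((matrix.n_taxa, len(uj)), dtype=np.uint32)
        for c, j in enumerate(uj):
            for i in range(matrix.n_taxa):
                m = 0
                for s in matrix.cells[i][j]:
                    m |= 1 << s
                self._fitch_masks[i, c] = m

        # Sankoff groups: characters bucketed by (state_count, ordered)
        self._groups: dict[tuple[int, bool], dict] = {}
        for p, (j, o) in enumerate(zip(active, ordered_flags)):
            k = matrix.state_count[j]
            key = (k, o)
            g = self._groups.setdefault(key, {"pos": [], "leaf": []})
            g["pos"].append(p)
        for (k, o), g in self._groups.items():
            pos = g["pos"]
            leaf = np.full((matrix.n_taxa, len(pos), k), INF, dtype=np.int64)
            for c, p in enumerate(pos):
                j = active[p]
                for i in range(matrix.n_taxa):
                    for s in matrix.cells[i][j]:
                        leaf[i, c, s] = 0
            g["leaf"] = leaf
            if o:
                cost = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            else:
                cost = 1 - np.eye(k, dtype=np.int64)
            g["cost"] = cost.astype(np.int64)

    # -- public ---------------------------------------------------------
    @property
    def n_active(self) -> int:
        return len(self.active)

    @property
    def sum_min(self) -> int:
        return int(np.dot(self.weights, self._mins))

    def length(self, tree: Tree) -> float:
        """Weighted total steps (equal weights: plain tree length)."""
        steps = self.per_char_steps(tree)
        return float(np.dot(self.weights, steps))

    def distortion(self, tree: Tree) -> float:
        steps = self.per_char_steps(tree)
        h = (steps - self._mins).astype(float)
        return float(np.sum(self.weights * h / (h + self.settings.K)))

    def objective(self, tree: Tree) -> float:
        if self.settings.weighting == "IMPLIED":
            return self.distortion(tree)
        return self.length(tree)

    def breakdown(self, tree: Tree) -> ScoreBreakdown:
        steps = self.per_char_steps(tree)
        return ScoreBreakdown(
            total_length=float(np.dot(self.weights, steps)),
            per_char_steps=steps,
            per_char_min=self._mins.copy(),
            per_char_max=self._maxs.copy(),
            char_indices=self.active.copy(),
            weights=self.weights.copy(),
        )

    # -- internals ------------------------------------------------------
    def _leaf_rows(self, tree: Tree) -> dict[int, int]:
        rows = {}
        for leaf in tree.leaves():
            if leaf.label not in self.taxon_index:
                raise TreeError(f"leaf {leaf.label!r} not scored in matrix")
            rows[id(leaf)] = self.taxon_index[leaf.label]
        return rows

    def per_char_steps(self, tree: Tree) -> np.ndarray:
        rows = self._leaf_rows(tree)
        post = list(tree.postorder())
        binary = all(len(nd.children) in (0, 2) for nd in post)
        steps = np.zeros(self.n_active, dtype=np.int64)
        if binary and self.unord_pos:
            steps[self.unord_pos] = self._fitch(post, rows)
            todo = [(key, g) for key, g in self._groups.items() if key[1]]
        else:
            todo = list(self._groups.items())
        for _, g in todo:
            dp = self._sankoff(post, rows, g)
            steps[g["pos"]] = dp
        return steps

    def _fitch(self, post, rows) -> np.ndarray:
        masks: dict[int, np.ndarray] = {}
        nsteps = np.zeros(len(self.unord_pos), dtype=np.int64)
        for nd in post:
            if nd.is_leaf():
                masks[id(nd)] = self._fitch_masks[rows[id(nd)]]
            elif len(nd.children) == 1:  # degree-2 pass-through
                masks[id(nd)] = masks[id(nd.children[0])]
            else:
                a = masks[id(nd.children[0])]
                b = masks[id(nd.children[1])]
                inter = a & b
                union = a | b
                empty = inter == 0
                nsteps += empty
                masks[id(nd)] = np.where(empty, union, inter)
        return nsteps

    def _sankoff(self, post, rows, group) -> np.ndarray:
        down = self._sankoff_down(post, rows, group)
        return down[id(post[-1])].min(axis=1)

    def _sankoff_down(self, post, rows, group) -> dict[int, np.ndarray]:
        cost = group["cost"]
        leaf = group["leaf"]
        dp: dict[int, np.ndarray] = {}
        for nd in post:
            if nd.is_leaf():
                dp[id(nd)] = leaf[rows[id(nd)]]
            else:
                tot = None
                for ch in nd.children:
                    child = dp[id(ch)]
                    # min_j (cost[s, j] + child[:, j]) for each s
                    contrib = (child[:, None, :] + cost[None, :, :]).min(axis=2)
                    tot = contrib if tot is None else tot + contrib
                dp[id(nd)] = tot
        return dp

    # -- branch support for the collapse rule ---------------------------
    def zero_min_length_branches(self, tree: Tree) -> list:
        """Internal non-root nodes whose subtending branch can carry zero
        changes in some optimal reconstruction of every character."""
        rows = self._leaf_rows(tree)
        post = list(tree.postorder())
        candidates = [nd for nd in post
                      if not nd.is_leaf() and nd.parent is not None]
        ok = {id(nd): True for nd in candidates}
        for _, g in self._groups.items():
            down = self._sankoff_down(post, rows, g)
            up = self._sankoff_up(tree, down, g)
            best = down[id(post[-1])].min(axis=1)  # per-char optimum
            for nd in candidates:
                if not ok[id(nd)]:
                    continue
                tied = (down[id(nd)] + up[id(nd)]).min(axis=1)
                if np.any(tied > best):
                    ok[id(nd)] = False
        return [nd for nd in candidates if ok[id(nd)]]

    def _sankoff_up(self, tree: Tree, down, group) -> dict[int, np.ndarray]:
        """up[v][c, s] = min cost of the tree outside subtree(v), given the
        parent-side endpoint of v's branch is in state s."""
        cost = group["cost"]
        nchars, k = down[id(tree.root)].shape
        up: dict[int, np.ndarray] = {}
        for nd in tree.preorder():
            if nd.parent is None:
                base = np.zeros((nchars, k), dtype=np.int64)
            else:
                # fold the cost outside subtree(nd) over nd's own branch:
                # base[c, s] = min_p (up[nd][c, p] + cost[p, s])
                pu = up[id(nd)]
                base = (pu[:, :, None] + cost[None, :, :]).min(axis=1)
            for ch in nd.children:
                sib = base.copy()
                for other in nd.children:
                    if other is ch:
                        continue
                    contrib = (down[id(other)][:, None, :]
                               + cost[None, :, :]).min(axis=2)
                    sib = sib + contrib
                up[id(ch)] = sib
        return up


# ---------------------------------------------------------- module-level
def char_steps(tree: Tree, matrix: CharacterMatrix, char_index: int,
               ordered: bool = False) -> int:
    """Minimum state changes for one character (1-based index) on a tree."""
    if not (1 <= char_index <= matrix.n_char):
        raise ValueError(f"character index {char_index} out of range")
    settings = CharacterSettings(
        ordered_set=frozenset([char_index]) if ordered else frozenset())
    sub = CharacterMatrix(
        taxa=list(matrix.taxa),
        cells=[[row[char_index - 1]] for row in matrix.cells],
        n_char=1,
        state_count=[matrix.state_count[char_index - 1]],
    )
    sub_settings = CharacterSettings(
        ordered_set=frozenset([1]) if ordered else frozenset())
    return int(TreeScorer(sub, sub_settings).per_char_steps(tree)[0])


def tree_length(tree: Tree, matrix: CharacterMatrix,
                settings: Optional[CharacterSettings] = None) -> ScoreBreakdown:
    return TreeScorer(matrix, settings).breakdown(tree)


def ensemble_indices(best_length: float, matrix: CharacterMatrix,
                     settings: Optional[CharacterSettings] = None,
                     informative_only: bool = False) -> tuple[float, float]:
    """(CI, RI) at the given best length; both rounded-ready, in [0, 1]."""
    if best_length <= 0:
        raise ValueError("best_length must be positive")
    scorer = TreeScorer(matrix, settings)
    m, g, w = scorer._mins, scorer._maxs, scorer.weights
    L = float(best_length)
    if informative_only:
        keep = g > m
        drop_len = float(np.dot(w[~keep], m[~keep]))
        m, g, w = m[keep], g[keep], w[keep]
        L = L - drop_len
    sum_m = float(np.dot(w, m))
    sum_g = float(np.dot(w, g))
    ci = sum_m / L
    if sum_g == sum_m:
        raise RIUndefinedError("no potential homoplasy: RI undefined")
    ri = (sum_g - L) / (sum_g - sum_m)
    return ci, ri


def iw_score(tree: Tree, matrix: CharacterMatrix,
             settings: CharacterSettings) -> float:
    """Total implied-weighting distortion D = sum_i h_i / (h_i + K)."""
    if settings.weighting != "IMPLIED":
        raise ValueError("settings must use IMPLIED weighting")
    return TreeScorer(matrix, settings).distortion(tree)


def zero_min_length_branches(tree: Tree, matrix: CharacterMatrix,
                             settings: Optional[CharacterSettings] = None) -> list:
    return TreeScorer(matrix, settings).zero_min_length_branches(tree)
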