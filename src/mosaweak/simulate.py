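"""Generators for synthetic fossil trees, discrete character matrices,
and a planted weak-spot fixture.

Everything is fully determined by (seed, config): trees come from a
forward birth--death simulation with Poissonian fossil sampling and no
extant sampling; matrices evolve under the symmetric k-state Markov chain
(with a nearest-neighbour stepwise chain for ordered morphoclines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .matrix_io import CharacterMatrix
from .tree import Node, Tree

__all__ = [
    "SimulationConfig", "FBDSimResult", "simulate_fbd_tree",
    "simulate_mk_matrix", "make_weakspot_fixture",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_taxa: int = 8                     # used by matrix-only helpers
    birth: float = 1.0                  # lambda (1/My)
    death: float = 0.5                  # mu
    psi: float = 1.0                    # fossil sampling rate
    origin: float = 10.0                # Mya
    n_characters: int = 50
    rate: float = 0.1                   # mean substitutions / My
    gamma_shape: float = 1.0
    state_counts: tuple = (2, 2, 2, 3)  # sampled uniformly per character
    ordered_fraction: float = 0.0
    variable_only: bool = False
    min_samples: int = 2

    def __post_init__(self):
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")
        for name in ("birth", "death", "psi", "rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FBDSimResult:
    tree: Tree
    n_samples: int
    n_sampled_ancestors: int
    total_branch_length: float          # of the complete (unpruned) process
    n_rejections: int


class _Rejected(Exception):
    pass


def simulate_fbd_tree(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      max_rejections: int = 10_000) -> FBDSimResult:
    """Forward birth--death with fossilization; extant sampling is zero,
    so unsampled surviving lineages are pruned.  A fossil with sampled
    descendants becomes a degree-2 sampled-ancestor node.

    Conditioned (by rejection) on at least ``config.min_samples`` fossils."""
    if config.birth <= 0:
        raise ValueError("birth rate must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rejections = 0
    while True:
        if rejections >= max_rejections:
            raise RuntimeError(
                f"{max_rejections} consecutive rejections; "
                "raise psi/origin or lower min_samples")
        try:
            tree, stats = _simulate_once(config, rng)
        except _Rejected:
            rejections += 1
            continue
        if stats["n_samples"] < config.min_samples:
            rejections += 1
            continue
        tree.set_lengths_from_ages()
        return FBDSimResult(
            tree=tree, n_samples=stats["n_samples"],
            n_sampled_ancestors=stats["n_sa"],
            total_branch_length=stats["total_length"],
            n_rejections=rejections)


def _simulate_once(config: SimulationConfig, rng) -> tuple:
    lam, mu, psi = config.birth, config.death, config.psi
    total = lam + mu + psi
    stats = {"n_samples": 0, "n_sa": 0, "total_length": 0.0, "events": 0}
    counter = [0]

    def sim(age: float) -> Optional[Node]:
        """Reconstructed sampled subtree of a lineage alive at ``age``."""
        stats["events"] += 1
        if stats["events"] > 100_000:
            raise _Rejected
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        next_age = age - wait
        if next_age <= 0:  # survives to the present, unsampled (rho = 0)
            stats["total_length"] += age
            return None
        stats["total_length"] += wait
        u = rng.random() * total
        if u < lam:  # birth
            left = sim(next_age)
            right = sim(next_age)
            if left is None and right is None:
                return None
            if left is None or right is None:
                return left if right is None else right
            nd = Node()
            nd.age = next_age
            nd.add_child(left)
            nd.add_child(right)
            return nd
        if u < lam + mu:  # death
            return None
        # fossil sample
        counter[0] += 1
        label = f"fossil_{counter[0]}"
        below = sim(next_age)
        stats["n_samples"] += 1
        nd = Node(label)
        nd.age = next_age
        if below is not None:
            nd.sampled_ancestor = True
            stats["n_sa"] += 1
            nd.add_child(below)
        return nd

    root = sim(config.origin)
    if root is None:
        raise _Rejected
    return Tree(root), stats


# ------------------------------------------------------------- Mk matrices
def _sym_transition(k: int, nu: float, rng, state: int) -> int:
    """One draw from the symmetric k-state chain after branch length nu."""
    p_change = (1.0 - np.exp(-k * nu / (k - 1))) / k
    u = rng.random()
    if u < 1 - (k - 1) * p_change:
        return state
    other = int((u - (1 - (k - 1) * p_change)) // p_change)
    others = [s for s in range(k) if s != state]
    return others[min(other, k - 2)]


def _stepwise_transition(k: int, nu: float, rng, state: int) -> int:
    """Nearest-neighbour (tridiagonal) chain, total leave-rate 1 in the
    interior; simulated by jumps (morphocline characters)."""
    t = 0.0
    while True:
        up = 0.5 if state < k - 1 else 0.0
        down = 0.5 if state > 0 else 0.0
        rate = up + down
        t += rng.exponential(1.0 / rate)
        if t >= nu:
            return state
        state = state + 1 if rng.random() * rate < up else state - 1


def simulate_mk_matrix(tree: Tree, config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None,
                       max_redraws: int = 1000) -> tuple[CharacterMatrix, dict]:
    """Evolve characters independently down ``tree`` (branch lengths =
    durations); returns (matrix, info) with info recording per-character
    state counts, gamma rate multipliers and ordered flags."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    leaves = tree.leaves()
    taxa = [lf.label for lf in leaves]
    n_ordered = int(round(config.ordered_fraction * config.n_characters))
    columns, state_counts, ordered_flags, rates = [], [], [], []
    for j in range(config.n_characters):
        ordered = j < n_ordered
        k = int(rng.choice(config.state_counts))
        if ordered:
            k = max(k, 3)
        rate_mult = (rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape)
                     if config.gamma_shape > 0 else 1.0)
        for attempt in range(max_redraws):
            col = _evolve_column(tree, k, config.rate * rate_mult, ordered, rng)
            if not config.variable_only or len(set(col.values())) > 1:
                break
        else:
            raise RuntimeError(
                f"character {j + 1}: could not produce a variable character "
                f"in {max_redraws} redraws (rate too low?)")
        columns.append([frozenset([col[id(lf)]]) for lf in leaves])
        state_counts.append(max(k, max(col[id(lf)] for lf in leaves) + 1))
        ordered_flags.append(ordered)
        rates.append(config.rate * rate_mult)
    cells = [[columns[j][i] for j in range(config.n_characters)]
             for i in range(len(taxa))]
    matrix = CharacterMatrix(taxa=taxa, cells=cells,
                             n_char=config.n_characters,
                             state_count=state_counts)
    info = {"ordered": ordered_flags, "rates": rates,
            "ordered_set": frozenset(j + 1 for j, o in enumerate(ordered_flags) if o)}
    return matrix, info


def _evolve_column(tree: Tree, k: int, rate: float, ordered: bool, rng) -> dict:
    trans = _stepwise_transition if ordered else _sym_transition
    states: dict[int, int] = {}
    out: dict[int, int] = {}
    for nd in tree.preorder():
        if nd.parent is None:
            states[id(nd)] = int(rng.integers(k))
        else:
            nu = rate * (nd.length or 0.0)
            if nu == 0:
                states[id(nd)] = states[id(nd.parent)]
            else:
                states[id(nd)] = trans(k, nu, rng, states[id(nd.parent)])
        if nd.is_leaf() or nd.sampled_ancestor:
            out[id(nd)] = states[id(nd)]
    return out


# ------------------------------------------------------- weak-spot fixture
def make_weakspot_fixture(seed: int = 0):
    """A 12-taxon matrix with a planted strategy-dependent weak spot.

    Returns (matrix, ordered_set, definitions, expected) where ``expected``
    maps definition name -> {"unordered": status, "ordered": status}.

    The FragileCladePlant morphocline characters pull taxon ``FX`` toward
    ``E1`` when scored additively, dissolving the {F1, F2, FX} clade that
    binary characters support; the StableCladePlant clade {S1, S2, S3} is
    untouched by the ordering choice."""
    from .definitions import APPLIES, SELF_DESTRUCTS, PhyloDefinition, Specifier

    taxa = ["OUT", "S1", "S2", "S3", "F1", "F2", "FX", "E1",
            "N1", "N2", "N3", "N4"]

    def char(ones: set, states: Optional[dict] = None) -> list:
        if states is None:
            states = {t: 1 for t in ones}
        return [states.get(t, 0) for t in taxa]

    chars: list[list[int]] = []
    ordered_idx: list[int] = []
    chars += [char({"S1", "S2", "S3"})] * 6
    chars += [char({"F1", "F2", "FX", "E1"})] * 3
    chars += [char({"F1", "F2", "FX"})] * 2
    chars += [char({"F1", "F2"})] * 2
    for _ in range(4):  # planted morphocline: E1 intermediate, FX extreme
        ordered_idx.append(len(chars) + 1)
        chars.append(char(set(), {"E1": 1, "FX": 2}))
    chars += [char({"N1", "N2"})] * 2
    chars += [char({"N3", "N4"})] * 2
    chars += [char({"N1", "N2", "N3", "N4"})] * 2

    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(len(chars)))
    chars = [chars[i] for i in perm]
    ordered_set = frozenset(perm.index(i - 1) + 1 for i in ordered_idx)

    cells = [[frozenset([chars[j][i]]) for j in range(len(chars))]
             for i in range(len(taxa))]
    state_count = [max(c) + 1 if max(c) > 0 else 2 for c in chars]
    matrix = CharacterMatrix(taxa=list(taxa), cells=cells, n_char=len(chars),
                             state_count=state_count)

    definitions = [
        PhyloDefinition(
            name="StableCladePlant", kind="NODE",
            internal=[Specifier(taxon="S1"), Specifier(taxon="S3")],
            external=[Specifier(taxon="OUT")]),
        PhyloDefinition(
            name="FragileCladePlant", kind="NODE",
            internal=[Specifier(taxon="F1"), Specifier(taxon="FX")],
            external=[Specifier(taxon="E1")]),
    ]
    expected = {
        "StableCladePlant": {"unordered": APPLIES, "ordered": APPLIES},
        "FragileCladePlant": {"unordered": APPLIES, "ordered": SELF_DESTRUCTS},
    }
    return matrix, ordered_set, definitions, expected
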