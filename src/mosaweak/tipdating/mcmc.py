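"""Metropolis–Hastings sampler over fossil trees (topology, node ages,
sampled-ancestor placements) and model parameters under the Mk likelihood
and the sampled-ancestor FBD tree prior.

The root age carries a uniform prior from the oldest tip age to a cap
(200 by default); tip ages are fixed at their calibration means unless
``sample_tip_ages`` is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, log
from typing import Optional

import numpy as np
from scipy.stats import lognorm

from ..matrix_io import CharacterMatrix, TipCalibration
from ..tree import Node, Tree
from .fbd import FBDParams, fbd_sa_log_prior
from .mk import MkModel, mk_log_likelihood

__all__ = ["ClockModel", "MCMCConfig", "PosteriorSample", "mcmc_run"]


@dataclass
class ClockModel:
    kind: str = "strict"            # "strict" or "lognormal"
    n_categories: Optional[int] = None   # default n_branches - 1

    def __post_init__(self):
        if self.kind not in ("strict", "lognormal"):
            raise ValueError(f"unknown clock model {self.kind!r}")


@dataclass
class MCMCConfig:
    generations: int = 100_000
    sample_interval: int = 100
    burnin_fraction: float = 0.2
    seed: int = 0
    root_max: float = 200.0
    likelihood_off: bool = False
    tree_prior_off: bool = False
    sample_tip_ages: bool = False
    prior_means: dict = field(default_factory=lambda: {
        "birth": 1.0, "death": 1.0, "psi": 1.0,
        "clock_rate": 1.0, "alpha": 1.0, "clock_scale": 0.3})
    move_weights: dict = field(default_factory=lambda: {
        "scale_param": 4.0, "node_age": 4.0, "root_age": 1.0,
        "sa_toggle": 2.0, "regraft": 3.0, "tip_age": 0.0})
    fixed_topology: bool = False
    fixed_parameters: tuple = ()    # parameter names excluded from moves


@dataclass
class PosteriorSample:
    trees: list
    params: dict                    # name -> np.ndarray
    log_posterior: np.ndarray
    sample_interval: int
    burnin_fraction: float
    acceptance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.trees)

    def post_burnin(self) -> "PosteriorSample":
        cut = int(len(self.trees) * self.burnin_fraction)
        return PosteriorSample(
            trees=self.trees[cut:],
            params={k: v[cut:] for k, v in self.params.items()},
            log_posterior=self.log_posterior[cut:],
            sample_interval=self.sample_interval,
            burnin_fraction=0.0,
            acceptance=self.acceptance)

    def sa_counts(self) -> np.ndarray:
        return np.array(
            [sum(1 for nd in t.postorder() if nd.sampled_ancestor)
             for t in self.trees], dtype=int)


# ------------------------------------------------------------------ state
class _State:
    def __init__(self, tree: Tree, params: dict, clock: ClockModel,
                 clock_cats: dict, tip_ages: TipCalibration):
        self.tree = tree
        self.params = params            # birth, death, psi, clock_rate, alpha, clock_scale
        self.clock = clock
        self.clock_cats = clock_cats    # id(node) -> category index
        self.tip_ages = tip_ages


class _Sampler:
    def __init__(self, matrix: CharacterMatrix, tip_ages: TipCalibration,
                 mk_model: MkModel, clock: ClockModel, config: MCMCConfig):
        self.matrix = matrix
        self.tip_ages = tip_ages
        self.mk_model = mk_model
        self.clock = clock
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.oldest_tip = tip_ages.oldest()
        for taxon, age in tip_ages.mean.items():
            if age <= 0:
                raise ValueError(f"extant tip {taxon!r} not allowed (rho = 0)")

    # ---- posterior components ----------------------------------------
    def log_likelihood(self, state: _State) -> float:
        if self.config.likelihood_off:
            return 0.0
        state.tree.set_lengths_from_ages()
        model = MkModel(gamma_shape=state.params["alpha"],
                        n_gamma=self.mk_model.n_gamma,
                        condition_on_variable=self.mk_model.condition_on_variable)
        rates = self.branch_rates(state)
        try:
            return mk_log_likelihood(state.tree, self.matrix, model,
                                     rate=state.params["clock_rate"],
                                     branch_rates=rates)
        except ValueError:
            return -inf

    def branch_rates(self, state: _State) -> Optional[dict]:
        if self.clock.kind == "strict":
            return None
        n_branches = sum(1 for nd in state.tree.postorder()
                         if nd.parent is not None)
        ncat = self.clock.n_categories or max(n_branches - 1, 1)
        scale = state.params["clock_scale"]
        probs = (2 * np.arange(ncat) + 1) / (2 * ncat)
        # lognormal with mean 1: location -scale^2/2
        quants = lognorm.ppf(probs, scale, scale=np.exp(-scale ** 2 / 2))
        out = {}
        for nd in state.tree.postorder():
            if nd.parent is None:
                continue
            cat = state.clock_cats.get(id(nd))
            if cat is None:
                cat = int(self.rng.integers(ncat))
                state.clock_cats[id(nd)] = cat
            out[id(nd)] = float(quants[min(cat, ncat - 1)])
        return out

    def log_tree_prior(self, state: _State) -> float:
        root_age = state.tree.root.age
        if not (self.oldest_tip <= root_age <= self.config.root_max):
            return -inf
        if self.config.tree_prior_off:
            return 0.0
        try:
            params = FBDParams(birth=state.params["birth"],
                               death=state.params["death"],
                               psi=state.params["psi"])
            return fbd_sa_log_prior(state.tree, params)
        except ValueError:
            return -inf

    def log_param_prior(self, state: _State) -> float:
        total = 0.0
        for name in ("birth", "death", "psi", "clock_rate", "alpha",
                     "clock_scale"):
            mean = self.config.prior_means[name]
            x = state.params[name]
            if x <= 0:
                return -inf
            total += -x / mean - log(mean)
        return total

    # ---- initialization ----------------------------------------------
    def initial_state(self) -> _State:
        rng = self.rng
        subtrees = []
        for taxon in self.matrix.taxa:
            nd = Node(taxon)
            nd.age = self.tip_ages.mean[taxon]
            subtrees.append(nd)
        while len(subtrees) > 1:
            i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
            b = subtrees.pop(j)
            a = subtrees.pop(i)
            parent = Node()
            parent.age = max(a.age, b.age) + float(rng.uniform(0.5, 3.0))
            parent.add_child(a)
            parent.add_child(b)
            subtrees.append(parent)
        tree = Tree(subtrees[0])
        if tree.root.age > self.config.root_max:
            raise ValueError("initial root age exceeded the cap; "
                             "check tip ages")
        params = {"birth": 1.0, "death": 0.5, "psi": 0.5,
                  "clock_rate": 0.05, "alpha": 1.0, "clock_scale": 0.3}
        return _State(tree, params, self.clock, {}, self.tip_ages)

    # ---- moves --------------------------------------------------------
    def propose(self, state: _State):
        """Returns (new_state, log_hastings, touched) or None.

        ``touched`` is a subset of {"lik", "tree", "param"} naming the
        posterior components the move can change."""
        cfg = self.config
        weights = dict(cfg.move_weights)
        if cfg.fixed_topology:
            weights["regraft"] = 0.0
            weights["sa_toggle"] = 0.0
        if not cfg.sample_tip_ages:
            weights["tip_age"] = 0.0
        names = [k for k, w in weights.items() if w > 0]
        probs = np.array([weights[k] for k in names])
        move = self.rng.choice(names, p=probs / probs.sum())
        return getattr(self, f"_move_{move}")(state)

    def _copy_state(self, state: _State) -> _State:
        tree = state.tree.copy()
        # carry clock categories across the copy by positional matching
        cats = {}
        for old, new in zip(state.tree.postorder(), tree.postorder()):
            if id(old) in state.clock_cats:
                cats[id(new)] = state.clock_cats[id(old)]
        return _State(tree, dict(state.params), state.clock, cats,
                      state.tip_ages)

    def _move_scale_param(self, state):
        candidates = [n for n in ("birth", "death", "psi", "clock_rate",
                                  "alpha", "clock_scale")
                      if n not in self.config.fixed_parameters]
        if self.clock.kind == "strict" and "clock_scale" in candidates:
            candidates.remove("clock_scale")
        if self.config.likelihood_off:
            candidates = [c for c in candidates
                          if c not in ("clock_rate", "alpha", "clock_scale")]
        if not candidates:
            return None
        name = candidates[int(self.rng.integers(len(candidates)))]
        new = self._copy_state(state)
        m = float(np.exp(0.5 * (self.rng.random() - 0.5)))
        new.params[name] = state.params[name] * m
        touched = {"param"}
        if name in ("birth", "death", "psi"):
            touched.add("tree")
        else:
            touched.add("lik")
        return new, log(m), touched

    def _bifurcations(self, tree: Tree, include_root: bool = True):
        return [nd for nd in tree.postorder()
                if len(nd.children) == 2 and (include_root or nd.parent is not None)]

    def _move_node_age(self, state):
        new = self._copy_state(state)
        nodes = self._bifurcations(new.tree, include_root=False)
        if not nodes:
            return None
        nd = nodes[int(self.rng.integers(len(nodes)))]
        lo = max(c.age for c in nd.children)
        hi = nd.parent.age
        if hi <= lo:
            return None
        nd.age = float(self.rng.uniform(lo, hi))
        return new, 0.0, {"lik", "tree"}

    def _move_root_age(self, state):
        new = self._copy_state(state)
        root = new.tree.root
        if len(root.children) != 2:
            return None
        lo = max(c.age for c in root.children)
        hi = self.config.root_max
        if hi <= lo:
            return None
        root.age = float(self.rng.uniform(lo, hi))
        return new, 0.0, {"lik", "tree"}

    def _move_tip_age(self, state):
        new = self._copy_state(state)
        leaves = [nd for nd in new.tree.postorder()
                  if (nd.is_leaf() or nd.sampled_ancestor)
                  and nd.label in new.tip_ages.range]
        if not leaves:
            return None
        nd = leaves[int(self.rng.integers(len(leaves)))]
        lo, hi = new.tip_ages.range[nd.label]
        if nd.children:
            lo = max(lo, nd.children[0].age)
        hi = min(hi, nd.parent.age if nd.parent else self.config.root_max)
        if hi <= lo:
            return None
        nd.age = float(self.rng.uniform(lo, hi))
        return new, 0.0, {"lik", "tree"}

    def _move_sa_toggle(self, state):
        new = self._copy_state(state)
        fossils = [nd for nd in new.tree.postorder()
                   if nd.label is not None and (nd.is_leaf() or nd.sampled_ancestor)]
        nd = fossils[int(self.rng.integers(len(fossils)))]
        if nd.sampled_ancestor:
            # expand: SA -> terminal leaf on a new bifurcation
            if nd.parent is None:
                return None
            child = nd.children[0]
            lo = max(nd.age, child.age)
            hi = nd.parent.age
            if hi <= lo:
                return None
            a = float(self.rng.uniform(lo, hi))
            leaf = Node(nd.label)
            leaf.age = nd.age
            nd.label = None
            nd.sampled_ancestor = False
            nd.age = a
            nd.add_child(leaf)
            return new, log(hi - lo), {"lik", "tree"}
        # collapse: terminal leaf -> SA on the sibling branch
        p = nd.parent
        if p is None or p.parent is None or len(p.children) != 2:
            return None
        sib = p.children[0] if p.children[1] is nd else p.children[1]
        if nd.age <= sib.age:
            return None  # SA must predate everything below it
        lo = max(nd.age, sib.age)
        hi = p.parent.age
        if hi <= lo:
            return None
        p.children.remove(nd)
        p.label = nd.label
        p.sampled_ancestor = True
        p.age = nd.age
        return new, -log(hi - lo), {"lik", "tree"}

    def _prune_candidates(self, tree: Tree):
        out = []
        for nd in tree.postorder():
            p = nd.parent
            if p is None or len(p.children) != 2:
                continue  # root or child of a sampled ancestor
            sib = p.children[0] if p.children[1] is nd else p.children[1]
            if p.parent is None and len(sib.children) != 2:
                continue  # sibling would become a non-bifurcating root
            out.append(nd)
        return out

    def _attach_options(self, tree: Tree, v_age: float):
        opts = []
        for nd in tree.postorder():
            if nd.parent is None:
                w = self.config.root_max - max(nd.age, v_age)
                if w > 0:
                    opts.append((nd, None, w))
            else:
                w = nd.parent.age - max(nd.age, v_age)
                if w > 0:
                    opts.append((nd, nd.parent, w))
        return opts

    def _move_regraft(self, state):
        new = self._copy_state(state)
        tree = new.tree
        cands = self._prune_candidates(tree)
        if not cands:
            return None
        n_prune_old = len(cands)
        v = cands[int(self.rng.integers(len(cands)))]
        p = v.parent
        sib = p.children[0] if p.children[1] is v else p.children[1]
        if p.parent is None:
            w_old = self.config.root_max - max(sib.age, v.age)
        else:
            w_old = p.parent.age - max(sib.age, v.age)
        # detach v, splice out p
        v.detach()
        if p.parent is None:
            sib.parent = None
            tree.root = sib
        else:
            gp = p.parent
            idx = gp.children.index(p)
            gp.children[idx] = sib
            sib.parent = gp
        opts = self._attach_options(tree, v.age)
        opts = [o for o in opts if o[0] is not v]
        if not opts:
            return None
        n_fwd = len(opts)
        target, tparent, w_new = opts[int(self.rng.integers(len(opts)))]
        joint = Node()
        joint.age = float(max(target.age, v.age) + self.rng.random() * w_new)
        if tparent is None:  # attach above the root
            target.parent = joint
            joint.children.append(target)
            joint.add_child(v)
            tree.root = joint
        else:
            idx = tparent.children.index(target)
            tparent.children[idx] = joint
            joint.parent = tparent
            joint.add_child(target)
            joint.add_child(v)
        n_prune_new = len(self._prune_candidates(tree))
        n_rev = len(self._attach_options_excluding(tree, v))
        if n_rev == 0 or n_prune_new == 0:
            return None
        log_hr = (log(n_prune_old) + log(n_fwd) + log(w_new)
                  - log(n_prune_new) - log(n_rev) - log(w_old))
        return new, log_hr, {"lik", "tree"}

    def _attach_options_excluding(self, tree: Tree, v: Node) -> list:
        """Reverse-move option count: attachments available after pruning
        v again (the tree minus v, approximated by excluding v's edge)."""
        p = v.parent
        sib = p.children[0] if p.children[1] is v else p.children[1]
        v.detach()
        if p.parent is None:
            old_root = tree.root
            sib_parent = sib.parent
            sib.parent = None
            tree.root = sib
            opts = self._attach_options(tree, v.age)
            sib.parent = sib_parent
            tree.root = old_root
            p.add_child(v)
        else:
            gp = p.parent
            idx = gp.children.index(p)
            gp.children[idx] = sib
            sib.parent = gp
            opts = self._attach_options(tree, v.age)
            gp.children[idx] = p
            sib.parent = p
            p.add_child(v)
            p.children.reverse()
        return [o for o in opts if o[0] is not v]

    # ---- main loop -----------------------------------------------------
    def run(self) -> PosteriorSample:
        cfg = self.config
        state = self.initial_state()
        comp = {
            "lik": self.log_likelihood(state),
            "tree": self.log_tree_prior(state),
            "param": self.log_param_prior(state),
        }
        post = sum(comp.values())
        tries = 0
        while not np.isfinite(post) and tries < 200:
            state = self.initial_state()
            comp = {"lik": self.log_likelihood(state),
                    "tree": self.log_tree_prior(state),
                    "param": self.log_param_prior(state)}
            post = sum(comp.values())
            tries += 1
        if not np.isfinite(post):
            raise RuntimeError(
                f"non-finite posterior at initialization: {comp}")
        trees, lp = [], []
        params: dict[str, list] = {k: [] for k in state.params}
        params["root_age"] = []
        accept = {"accepted": 0, "proposed": 0}
        for gen in range(cfg.generations + 1):
            prop = self.propose(state)
            if prop is not None:
                new_state, log_hr, touched = prop
                accept["proposed"] += 1
                new_comp = dict(comp)
                for key in touched:
                    fn = {"lik": self.log_likelihood,
                          "tree": self.log_tree_prior,
                          "param": self.log_param_prior}[key]
                    new_comp[key] = fn(new_state)
                new_post = sum(new_comp.values())
                if (np.isfinite(new_post)
                        and log(self.rng.random() + 1e-300)
                        < new_post - post + log_hr):
                    state, comp, post = new_state, new_comp, new_post
                    accept["accepted"] += 1
            if gen % cfg.sample_interval == 0:
                trees.append(state.tree.copy())
                for k, v in state.params.items():
                    params[k].append(v)
                params["root_age"].append(state.tree.root.age)
                lp.append(post)
        for t in trees:
            t.set_lengths_from_ages()
        return PosteriorSample(
            trees=trees,
            params={k: np.array(v) for k, v in params.items()},
            log_posterior=np.array(lp),
            sample_interval=cfg.sample_interval,
            burnin_fraction=cfg.burnin_fraction,
            acceptance=accept)


def mcmc_run(matrix: CharacterMatrix, tip_ages: TipCalibration,
             mk_model: Optional[MkModel] = None,
             clock: Optional[ClockModel] = None,
             config: Optional[MCMCConfig] = None,
             initial_tree: Optional[Tree] = None) -> PosteriorSample:
    """Run the tip-dating chain and return the (unthinned-by-burnin)
    posterior sample; use :meth:`PosteriorSample.post_burnin` downstream."""
    sampler = _Sampler(matrix, tip_ages, mk_model or MkModel(),
                       clock or ClockModel(), config or MCMCConfig())
    if initial_tree is not None:
        orig = sampler.initial_state

        def seeded() -> _State:
            st = orig()
            st.tree = initial_tree.copy()
            return st

        sampler.initial_state = seeded
    return sampler.run()
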