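"""Likelihood of discrete characters under the symmetric k-state Markov
model, with discrete-gamma rate variation and optional conditioning on
characters being variable (matrices that exclude constant characters)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import gamma as gamma_dist

from ..matrix_io import CharacterMatrix
from ..tree import Tree

__all__ = ["MkModel", "gamma_category_rates", "mk_log_likelihood"]


@dataclass
class MkModel:
    gamma_shape: float = 1.0
    n_gamma: int = 4
    condition_on_variable: bool = True

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_gamma < 1:
            raise ValueError("need at least one rate category")


def gamma_category_rates(shape: float, n: int) -> np.ndarray:
    """Median-of-quantile discretization of Gamma(shape, mean 1),
    renormalized to mean exactly 1."""
    if n == 1:
        return np.array([1.0])
    probs = (2 * np.arange(n) + 1) / (2 * n)
    rates = gamma_dist.ppf(probs, shape, scale=1.0 / shape)
    return rates / rates.mean()


def _transition_factors(k: int, nu: np.ndarray):
    """(p_diff, p_same - p_diff) for the symmetric k-state chain."""
    e = np.exp(-k * nu / (k - 1))
    p_diff = (1.0 - e) / k
    return p_diff, e


def mk_log_likelihood(tree: Tree, matrix: CharacterMatrix,
                      model: Optional[MkModel] = None,
                      rate: float = 1.0,
                      branch_rates: Optional[dict] = None) -> float:
    """Pruning-algorithm log likelihood.

    Branch lengths on the tree are durations; the expected number of
    changes on a branch is ``length * rate * branch_rates[node] * g`` for
    each gamma category rate ``g``.  Sampled-ancestor nodes contribute
    their observed states at an internal point of the tree.  With
    ``condition_on_variable`` each character's likelihood is divided by
    the probability of being variable given its state count.
    """
    model = model or MkModel()
    cat_rates = gamma_category_rates(model.gamma_shape, model.n_gamma)
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    post = list(tree.postorder())
    for nd in post:
        if nd.parent is not None and (nd.length is None or nd.length < 0):
            raise ValueError(f"branch above {nd.label or 'internal node'} "
                             "has no non-negative duration")

    active = matrix.active_indices()
    groups: dict[int, list[int]] = {}
    for j in active:
        groups.setdefault(matrix.state_count[j], []).append(j)

    total = 0.0
    for k, js in groups.items():
        tipvec = {}
        for label, i in taxon_index.items():
            v = np.zeros((len(js), k))
            for c, j in enumerate(js):
                for s in matrix.cells[i][j]:
                    v[c, s] = 1.0
            tipvec[label] = v
        ll = _group_log_likelihood(post, tipvec, k, len(js), cat_rates,
                                   rate, branch_rates)
        if model.condition_on_variable:
            const = {label: np.eye(k) for label in tipvec}  # pattern s per row
            log_const = _group_log_likelihood(post, const, k, k, cat_rates,
                                              rate, branch_rates)
            p_const = np.exp(log_const).sum()
            if p_const >= 1.0:
                raise ValueError("constant-pattern probability reached 1; "
                                 "cannot condition on variability")
            ll = ll - np.log1p(-p_const)
        if not np.all(np.isfinite(ll)):
            bad = js[int(np.argmin(np.isfinite(ll)))]
            raise ValueError(f"non-finite likelihood at character {bad + 1}")
        total += float(ll.sum())
    return total


def _group_log_likelihood(post, tipvec, k, nchars, cat_rates,
                          rate, branch_rates) -> np.ndarray:
    """Per-character log likelihoods for one state-count group."""
    ncat = len(cat_rates)
    partial: dict[int, np.ndarray] = {}    # (nchars, ncat, k)
    scale_log: dict[int, np.ndarray] = {}  # (nchars,)
    for nd in post:
        if nd.is_leaf():
            p = np.repeat(tipvec[nd.label][:, None, :], ncat, axis=1)
            s = np.zeros(nchars)
        else:
            p = np.ones((nchars, ncat, k))
            s = np.zeros(nchars)
            for ch in nd.children:
                br = 1.0 if branch_rates is None else branch_rates.get(id(ch), 1.0)
                nu = (ch.length or 0.0) * rate * br * cat_rates  # (ncat,)
                p_diff, e = _transition_factors(k, nu)
                cp = partial[id(ch)]
                tot = cp.sum(axis=2, keepdims=True)
                down = p_diff[None, :, None] * tot + e[None, :, None] * cp
                p = p * down
                s = s + scale_log[id(ch)]
            if nd.label is not None and nd.label in tipvec:
                # sampled ancestor: its own observation applies here
                p = p * tipvec[nd.label][:, None, :]
            mx = p.max(axis=(1, 2))
            mx = np.where(mx > 0, mx, 1.0)
            p = p / mx[:, None, None]
            s = s + np.log(mx)
        partial[id(nd)] = p
        scale_log[id(nd)] = s
    root = post[-1]
    lik = partial[id(root)].mean(axis=1).sum(axis=1) / k  # cat weights, root freq
    with np.errstate(divide="ignore"):
        return np.log(lik) + scale_log[id(root)]
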