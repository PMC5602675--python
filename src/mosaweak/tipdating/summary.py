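"""Posterior summaries: maximum-clade-credibility tree, sampled-ancestor
histogram, effective sample sizes, and HPD intervals."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..tree import Tree
from .mcmc import PosteriorSample

__all__ = ["mcct", "sampled_ancestor_histogram", "ess", "hpd_interval"]


def _tree_clades_with_ages(tree: Tree):
    leafsets = tree.node_leafsets()
    out = {}
    for nd in tree.postorder():
        if not nd.is_leaf():
            out[leafsets[id(nd)]] = nd.age
    return out


def mcct(sample: PosteriorSample | Sequence[Tree]) -> Tree:
    """The sampled tree maximizing the product of its clades' posterior
    frequencies; node ages annotated with the mean and 95% HPD over the
    samples containing each clade."""
    trees = list(sample.trees if isinstance(sample, PosteriorSample) else sample)
    if not trees:
        raise ValueError("empty posterior sample")
    n = len(trees)
    counts: dict[frozenset, int] = {}
    ages: dict[frozenset, list] = {}
    percall = []
    for t in trees:
        cl = _tree_clades_with_ages(t)
        percall.append(cl)
        for c, age in cl.items():
            counts[c] = counts.get(c, 0) + 1
            if age is not None:
                ages.setdefault(c, []).append(age)
    best_i, best_score = 0, -np.inf
    for i, cl in enumerate(percall):
        score = float(sum(np.log(counts[c] / n) for c in cl))
        if score > best_score:
            best_i, best_score = i, score
    tree = trees[best_i].copy()
    leafsets = tree.node_leafsets()
    for nd in tree.postorder():
        if nd.is_leaf():
            continue
        clade = leafsets[id(nd)]
        vals = np.array(ages.get(clade, []))
        if vals.size:
            lo, hi = hpd_interval(vals, 0.95)
            nd.label = nd.label or (
                f"pp={counts[clade] / n:.2f}_age={vals.mean():.2f}"
                f"_hpd={lo:.2f}-{hi:.2f}")
    return tree


def sampled_ancestor_histogram(sample: PosteriorSample):
    """(histogram dict count -> proportion, central 95% interval)."""
    counts = sample.sa_counts()
    vals, freq = np.unique(counts, return_counts=True)
    hist = {int(v): f / len(counts) for v, f in zip(vals, freq)}
    lo, hi = np.percentile(counts, [2.5, 97.5])
    return hist, (int(np.floor(lo)), int(np.ceil(hi)))


def ess(trace: Sequence[float]) -> float:
    """Autocorrelation-time ESS (initial positive-sum truncation).

    Constant traces return the sample count (degenerate); traces with net
    negative autocorrelation can legitimately exceed the sample count."""
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    var = x.var()
    if var == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (var * n)
    if acf[1] < 0:
        # net negative autocorrelation (e.g. alternating traces): the
        # chain mixes better than iid; report ESS > n, bounded.
        tau = max(1.0 + 2.0 * float(acf[1]), 0.1)
        return float(n / tau)
    tau = 1.0
    for lag in range(1, n // 2):
        pair = acf[lag] + (acf[lag + 1] if lag + 1 < n else 0.0)
        if pair < 0:
            break
        tau += 2.0 * acf[lag]
    tau = max(tau, 1e-3)
    return float(n / tau)


def hpd_interval(values: np.ndarray, mass: float = 0.95):
    """Shortest interval containing the requested posterior mass."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    m = max(1, int(np.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])
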