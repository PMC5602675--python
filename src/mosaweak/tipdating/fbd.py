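"""Fossilized birth–death tree prior with sampled ancestors and no
extant sampling (all samples are fossils).

The log density is assembled from per-event factors: every bifurcation
at age x contributes ``log lambda + log q(x)``; every terminal fossil at
age y contributes ``log psi + log p0(y) - log q(y)`` (its lineage leaves
no further samples); every sampled ancestor contributes ``log psi`` only
(no branching event, no extinct side branch).  Conditioning is either on
a known process origin (single stem, at least one sample) or on the root
bifurcation age (two stems, each with at least one sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log, sqrt
from typing import Optional

from ..tree import Tree

__all__ = ["FBDParams", "log_q", "log_p0", "fbd_sa_log_prior"]

NEG_INF = float("-inf")


@dataclass
class FBDParams:
    birth: float                     # lambda, 1/My
    death: float                     # mu
    psi: float                       # fossil sampling rate
    rho: float = 0.0                 # extant sampling, fixed at zero

    def __post_init__(self):
        if self.birth <= 0:
            raise ValueError("birth rate must be positive")
        if self.death < 0 or self.psi < 0:
            raise ValueError("rates must be non-negative")
        if self.rho != 0.0:
            raise ValueError("extant sampling is fixed at rho = 0")

    def c1c2(self) -> tuple:
        lam, mu, psi = self.birth, self.death, self.psi
        c1 = sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
        if c1 == 0:
            raise ValueError("degenerate parameters (c1 = 0)")
        c2 = -(lam - mu - psi) / c1
        return c1, c2


def log_q(t: float, params: FBDParams) -> float:
    """log of the q(t) propagator along an observed lineage."""
    c1, c2 = params.c1c2()
    e = exp(-c1 * t)
    denom = e * (1 - c2) + (1 + c2)
    return log(4.0) - c1 * t - 2.0 * log(denom)


def p0(t: float, params: FBDParams) -> float:
    """Probability that a lineage alive at age t leaves no sample."""
    lam, mu, psi = params.birth, params.death, params.psi
    c1, c2 = params.c1c2()
    e = exp(-c1 * t)
    frac = (e * (1 - c2) - (1 + c2)) / (e * (1 - c2) + (1 + c2))
    return (lam + mu + psi + c1 * frac) / (2 * lam)


def log_p0(t: float, params: FBDParams) -> float:
    v = p0(t, params)
    return log(v) if v > 0 else NEG_INF


def fbd_sa_log_prior(tree: Tree, params: FBDParams,
                     origin: Optional[float] = None,
                     age_tol: float = 1e-9) -> float:
    """Log density of a sampled-ancestor fossil tree.

    With ``origin`` given, the process starts as a single lineage at that
    age (must predate the root) and is conditioned on >=1 sample;
    otherwise it is conditioned on the root bifurcation age with each of
    the two stems carrying >=1 sample.
    """
    lam, psi = params.birth, params.psi
    n_samples = 0
    terms = 0.0
    for nd in tree.postorder():
        if nd.age is None:
            raise ValueError("all nodes need ages for the FBD density")
        if nd.is_leaf():
            n_samples += 1
            if nd.age <= age_tol:
                raise ValueError(
                    f"extant (age-0) sample {nd.label!r} has probability zero "
                    "under rho = 0")
            if psi == 0:
                return NEG_INF
            terms += log(psi) + log_p0(nd.age, params) - log_q(nd.age, params)
        elif len(nd.children) == 1:
            if not nd.sampled_ancestor:
                raise ValueError("degree-2 node without sampled-ancestor mark")
            n_samples += 1
            if psi == 0:
                return NEG_INF
            terms += log(psi)
        elif len(nd.children) == 2:
            if nd.parent is None and origin is None:
                continue  # root factor handled by the conditioning below
            terms += log(lam) + log_q(nd.age, params)
        else:
            raise ValueError("FBD density requires binary trees "
                             "(plus degree-2 sampled ancestors)")
    if n_samples == 0:
        raise ValueError("tree has no samples")
    root_age = tree.root.age
    if origin is not None:
        if origin + age_tol < root_age:
            return NEG_INF
        terms += log_q(origin, params) - _log1m_p0(origin, params)
    else:
        if tree.root.is_leaf() or len(tree.root.children) == 1:
            raise ValueError("root-conditioned density needs a root bifurcation")
        terms += 2.0 * (log_q(root_age, params) - _log1m_p0(root_age, params))
    return terms


def _log1m_p0(t: float, params: FBDParams) -> float:
    v = 1.0 - p0(t, params)
    if v <= 0:
        return NEG_INF
    return log(v)


def sample_fbd_parameters(tree: Tree, origin: float,
                          n_samples: int = 4000, thin: int = 5,
                          burnin: int = 2000, seed: int = 0,
                          prior_means=(1.0, 1.0, 1.0)):
    """Posterior sample of (birth, death, psi) given a fixed dated tree.

    The tree is the data; the target is the origin-conditioned FBD density
    times independent exponential priors.  Returns a dict of arrays."""
    import numpy as np

    rng = np.random.default_rng(seed)
    names = ("birth", "death", "psi")
    x = {"birth": 1.0, "death": 0.5, "psi": 1.0}

    def logpost(v) -> float:
        if any(val <= 0 for val in v.values()):
            return NEG_INF
        lp = sum(-v[n] / m - log(m) for n, m in zip(names, prior_means))
        try:
            dens = fbd_sa_log_prior(
                tree, FBDParams(v["birth"], v["death"], v["psi"]),
                origin=origin)
        except ValueError:
            return NEG_INF
        return lp + dens

    cur = logpost(x)
    out = {n: [] for n in names}
    total = burnin + n_samples * thin
    for it in range(total):
        name = names[it % 3]
        prop = dict(x)
        m = float(np.exp(0.6 * (rng.random() - 0.5)))
        prop[name] = x[name] * m
        lp = logpost(prop)
        if np.isfinite(lp) and log(rng.random() + 1e-300) < lp - cur + log(m):
            x, cur = prop, lp
        if it >= burnin and (it - burnin) % thin == 0:
            for n in names:
                out[n].append(x[n])
    return {n: np.array(v) for n, v in out.items()}
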