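"""Evaluation of node- and branch-based phylogenetic clade definitions on
rooted trees, with self-destruction detection and a cross-analysis
weak-spot report.

A definition names a clade through *specifiers*: leaf taxa (or composite
``NODE_OF(...)`` clades) that must be inside (internal) or outside
(external) the named clade.  A name *self-destructs* on a topology when
an external specifier falls inside the smallest clade forced by the
internal specifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .tree import Tree, TreeError

__all__ = [
    "Specifier", "PhyloDefinition", "DefinitionOutcome", "WeakSpotReport",
    "ProxyMap", "resolve_specifiers", "evaluate_definition",
    "evaluate_node_based", "evaluate_branch_based", "weak_spot_report",
]

APPLIES = "APPLIES"
SELF_DESTRUCTS = "SELF_DESTRUCTS"
NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class Specifier:
    taxon: Optional[str] = None
    node_of: Optional[tuple] = None     # composite, clade-valued specifier

    def __post_init__(self):
        if (self.taxon is None) == (self.node_of is None):
            raise ValueError("specifier is either a taxon or a node_of composite")

    def species(self) -> tuple:
        return (self.taxon,) if self.taxon else tuple(self.node_of)

    def __str__(self):
        if self.taxon:
            return self.taxon
        return "node_of(" + ", ".join(self.node_of) + ")"


@dataclass
class PhyloDefinition:
    name: str
    kind: str                       # "NODE" or "BRANCH"
    internal: list                  # list[Specifier]
    external: list = field(default_factory=list)
    authorship: str = ""

    def __post_init__(self):
        if self.kind not in ("NODE", "BRANCH"):
            raise ValueError(f"{self.name}: unknown definition kind {self.kind!r}")
        if not self.internal:
            raise ValueError(f"{self.name}: internal specifier list is empty")
        species = [s for sp in self.internal + self.external for s in sp.species()]
        if len(species) != len(set(species)):
            raise ValueError(f"{self.name}: repeated specifier taxa")
        if self.kind == "NODE" and len(self.internal) < 2 and not self.external:
            raise ValueError(
                f"{self.name}: node-based needs >=2 internals or qualifying externals")


@dataclass
class DefinitionOutcome:
    status: str
    clade: Optional[frozenset] = None
    reason: str = ""

    def __post_init__(self):
        if (self.status == APPLIES) != bool(self.clade):
            raise ValueError("clade must be non-empty iff status is APPLIES")


class ProxyMap:
    """Maps specifier species to matrix OTU labels.

    Resolution order: exact OTU match, explicit override entry, then a
    genus-level fallback when exactly one OTU shares the genus.  Ambiguous
    fallbacks resolve to nothing (an explicit entry is then required)."""

    def __init__(self, overrides: Optional[dict] = None):
        self.overrides = dict(overrides or {})

    @classmethod
    def from_tsv(cls, path) -> "ProxyMap":
        overrides = {}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("species", "specifier"):
                continue
            overrides[parts[0]] = parts[1] if len(parts) > 1 and parts[1] else None
        return cls(overrides)

    def resolve(self, species: str, otus: Sequence[str]) -> Optional[str]:
        if species in otus:
            return species
        if species in self.overrides:
            target = self.overrides[species]
            return target if target in otus else None
        genus = species.split()[0]
        hits = [o for o in otus if o.split()[0] == genus or o.split("_")[0] == genus]
        return hits[0] if len(hits) == 1 else None


def resolve_specifiers(definition: PhyloDefinition, tree: Tree,
                       proxy_map: Optional[ProxyMap] = None):
    """Resolve each specifier to a leaf set on the tree.

    Returns (internal_leafsets, external_leafsets, unresolved) where each
    leafset is the resolved leaf for a taxon specifier or the MRCA leaf
    set for a composite; unresolved is a list of (specifier, where)."""
    proxy_map = proxy_map or ProxyMap()
    otus = sorted(tree.leaf_labels())
    unresolved = []

    def one(sp: Specifier, where: str):
        leaves = []
        for species in sp.species():
            hit = proxy_map.resolve(species, otus)
            if hit is None:
                unresolved.append((sp, where))
                return None
            leaves.append(hit)
        if sp.taxon is not None:
            return frozenset(leaves)
        return tree.mrca(leaves).leaf_labels()

    internal = [one(sp, "internal") for sp in definition.internal]
    external = [one(sp, "external") for sp in definition.external]
    return internal, external, unresolved


def evaluate_node_based(definition: PhyloDefinition, tree: Tree,
                        proxy_map: Optional[ProxyMap] = None) -> DefinitionOutcome:
    """Least inclusive clade containing all internals; externals are
    qualifying clauses that trigger self-destruction if they intrude."""
    return _evaluate(definition, tree, proxy_map, kind="NODE")


def evaluate_branch_based(definition: PhyloDefinition, tree: Tree,
                          proxy_map: Optional[ProxyMap] = None) -> DefinitionOutcome:
    """Most inclusive clade containing the internals but no external."""
    return _evaluate(definition, tree, proxy_map, kind="BRANCH")


def evaluate_definition(definition: PhyloDefinition, tree: Tree,
                        proxy_map: Optional[ProxyMap] = None) -> DefinitionOutcome:
    return _evaluate(definition, tree, proxy_map, kind=definition.kind)


def _evaluate(definition, tree, proxy_map, kind) -> DefinitionOutcome:
    internal, external, unresolved = resolve_specifiers(definition, tree, proxy_map)
    internal_bad = [sp for sp, where in unresolved if where == "internal"]
    if internal_bad:
        return DefinitionOutcome(
            status=NOT_EVALUABLE,
            reason="unresolved internal specifier(s): "
                   + "; ".join(str(sp) for sp in internal_bad))
    # unresolved externals cannot intrude: drop them but note it
    external = [e for e in external if e is not None]
    note = ""
    if any(where == "external" for _, where in unresolved):
        missing = [str(sp) for sp, where in unresolved if where == "external"]
        note = f" (external specifier(s) absent from tree: {'; '.join(missing)})"

    anchor_leaves = set().union(*internal)
    mrca = tree.mrca(anchor_leaves)
    leafsets = tree.node_leafsets()
    mrca_set = leafsets[id(mrca)]
    intruders = [e for e in external if e & mrca_set]
    if intruders:
        names = ", ".join(sorted(min(e) for e in intruders))
        return DefinitionOutcome(
            status=SELF_DESTRUCTS,
            reason=f"external specifier(s) inside MRCA(internals): {names}" + note)
    if kind == "NODE":
        return DefinitionOutcome(status=APPLIES, clade=mrca_set,
                                 reason="node-based clade at MRCA" + note)
    # branch-based: walk rootward while no external intrudes
    node = mrca
    while node.parent is not None:
        parent_set = leafsets[id(node.parent)]
        if any(e & parent_set for e in external):
            break
        node = node.parent
    return DefinitionOutcome(status=APPLIES, clade=leafsets[id(node)],
                             reason="branch-based clade" + note)


# --------------------------------------------------------------- reporting
CONSISTENT = "CONSISTENT"
STRATEGY_DEPENDENT = "STRATEGY_DEPENDENT"
UNSUPPORTED = "UNSUPPORTED"


@dataclass
class WeakSpotReport:
    names: list
    run_ids: list
    status: dict                    # (name, run_id) -> DefinitionOutcome
    applies_fraction: dict = field(default_factory=dict)  # (name, run_id) -> float
    supports: dict = field(default_factory=dict)          # (name, run_id) -> dict
    summary: dict = field(default_factory=dict)           # name -> classification

    def to_rows(self) -> list[dict]:
        rows = []
        for name in self.names:
            for run in self.run_ids:
                out = self.status[(name, run)]
                row = {
                    "name": name, "run": run, "status": out.status,
                    "clade": ";".join(sorted(out.clade)) if out.clade else "",
                    "applies_fraction": self.applies_fraction.get((name, run), ""),
                    "reason": out.reason,
                }
                row.update(self.supports.get((name, run), {}))
                rows.append(row)
        return rows


def weak_spot_report(definitions: Sequence[PhyloDefinition],
                     runs: dict,
                     proxy_map: Optional[ProxyMap] = None,
                     supports: Optional[dict] = None) -> WeakSpotReport:
    """Evaluate every definition on every run.

    ``runs`` maps run-id -> either a consensus Tree or a dict with keys
    ``consensus`` (Tree) and optional ``trees`` (underlying optima, used
    for the applies-in-k-of-N fraction).  ``supports`` maps
    (name, run_id) -> dict of support values to carry into the report."""
    run_ids = list(runs)
    names = [d.name for d in definitions]
    status, fraction = {}, {}
    for d in definitions:
        for rid in run_ids:
            entry = runs[rid]
            consensus = entry["consensus"] if isinstance(entry, dict) else entry
            out = evaluate_definition(d, consensus, proxy_map)
            status[(d.name, rid)] = out
            if isinstance(entry, dict) and entry.get("trees"):
                trees = entry["trees"]
                k = sum(1 for t in trees
                        if evaluate_definition(d, t, proxy_map).status == APPLIES)
                fraction[(d.name, rid)] = k / len(trees)
    summary = {}
    for name in names:
        st = [status[(name, rid)].status for rid in run_ids]
        if all(s == APPLIES for s in st):
            summary[name] = CONSISTENT
        elif any(s == APPLIES for s in st):
            summary[name] = STRATEGY_DEPENDENT
        else:
            summary[name] = UNSUPPORTED
    return WeakSpotReport(names=names, run_ids=run_ids, status=status,
                          applies_fraction=fraction,
                          supports=supports or {}, summary=summary)
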