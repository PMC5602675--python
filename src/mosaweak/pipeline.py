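"""Orchestration of the full analysis battery: equal-weights and
implied-weighting parsimony (ordered and unordered), single-outgroup
reruns, a Bayesian tip-dating run, supports for the equal-weights runs,
and the consolidated weak-spot report."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, packaged_data
from .definitions import ProxyMap, weak_spot_report
from .matrix_io import (CharacterMatrix, CharacterSettings, TipCalibration,
                        read_definitions, read_ordered_set, read_tip_ages,
                        read_tnt_matrix)
from .parsimony import RIUndefinedError, ensemble_indices
from .search import SearchConfig, TreeSet, search_battery
from .support import bootstrap, bremer_support, majority_consensus, strict_consensus
from .tree import Tree, write_nexus_trees

__all__ = ["RunSpec", "RunManifest", "default_manifest", "run_battery",
           "single_outgroup_run"]


@dataclass
class RunSpec:
    id: str
    strategy: str                   # EQUAL | IW | SINGLE_OUTGROUP | BAYES
    ordered: bool = False
    K: Optional[float] = None
    keep_taxon: Optional[str] = None
    seed: int = 0
    overrides: dict = field(default_factory=dict)


@dataclass
class RunManifest:
    matrix_path: str
    ages_path: Optional[str] = None
    ordered_set_path: Optional[str] = None
    definitions_path: Optional[str] = None
    proxies_path: Optional[str] = None
    root_taxon: Optional[str] = None
    outgroups: list = field(default_factory=list)   # the three basal OTUs
    runs: list = field(default_factory=list)
    n_replicates: int = 25
    bootstrap_reps: int = 500
    bootstrap_search_replicates: int = 10
    bayes_generations: int = 1_000_000
    bayes_sample_interval: int = 500

    def __post_init__(self):
        ids = [r.id for r in self.runs]
        if len(ids) != len(set(ids)):
            raise ValueError("run ids must be unique")

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        runs = [RunSpec(**r) for r in raw.pop("runs", [])]
        return cls(runs=runs, **raw)


def default_manifest(matrix_path: str, ages_path: Optional[str] = None,
                     root_taxon: str = "Adriosaurus suessi",
                     outgroups: Optional[list] = None,
                     seed: int = 0, **kwargs) -> RunManifest:
    """The twelve-run battery: 2 equal-weights, 6 implied-weighting,
    3 single-outgroup, 1 Bayesian."""
    outgroups = outgroups or ["Adriosaurus suessi", "Dolichosaurus longicollis",
                              "Pontosaurus kornhuberi"]
    runs = [
        RunSpec(id="equal_unordered", strategy="EQUAL", ordered=False, seed=seed),
        RunSpec(id="equal_ordered", strategy="EQUAL", ordered=True, seed=seed),
    ]
    for K in (3, 6, 9):
        runs.append(RunSpec(id=f"iw_k{K}_unordered", strategy="IW",
                            ordered=False, K=float(K), seed=seed))
        runs.append(RunSpec(id=f"iw_k{K}_ordered", strategy="IW",
                            ordered=True, K=float(K), seed=seed))
    for taxon in outgroups:
        short = taxon.split()[0].lower()
        runs.append(RunSpec(id=f"single_outgroup_{short}",
                            strategy="SINGLE_OUTGROUP", keep_taxon=taxon,
                            seed=seed))
    runs.append(RunSpec(id="bayes_fbd", strategy="BAYES", seed=seed))
    return RunManifest(matrix_path=matrix_path, ages_path=ages_path,
                       root_taxon=root_taxon, outgroups=outgroups,
                       runs=runs, **kwargs)


def single_outgroup_run(matrix: CharacterMatrix, keep_taxon: str,
                        outgroups: list,
                        settings: Optional[CharacterSettings] = None,
                        config: Optional[SearchConfig] = None) -> TreeSet:
    """Deactivate the other designated outgroup OTUs and search rooted on
    the kept one."""
    if keep_taxon not in outgroups:
        raise ValueError(f"{keep_taxon!r} is not one of the designated outgroups")
    if keep_taxon not in matrix.taxa:
        raise ValueError(f"unknown taxon {keep_taxon!r}")
    drop = [t for t in outgroups if t != keep_taxon]
    keep = [t for t in matrix.taxa if t not in drop]
    sub = matrix.subset_taxa(keep)
    config = config or SearchConfig(n_replicates=10)
    cfg = SearchConfig(n_replicates=config.n_replicates, seed=config.seed,
                       swap=config.swap, max_saved_trees=config.max_saved_trees,
                       collapse_rule=config.collapse_rule,
                       root_taxon=keep_taxon)
    return search_battery(sub, settings, cfg)


def run_battery(manifest: RunManifest, out_dir) -> dict:
    """Execute every run; per-run artifacts under ``out_dir/<run id>/``.

    Returns {"report": WeakSpotReport, "runs": {...}, "errors": {...}}.
    Failures are recorded and the battery continues."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_tnt_matrix(manifest.matrix_path)
    ordered = (read_ordered_set(manifest.ordered_set_path)
               if manifest.ordered_set_path
               else read_ordered_set(packaged_data("ordered_chars.txt")))
    defs = read_definitions(manifest.definitions_path or
                            packaged_data("table1.json"))
    proxies = (ProxyMap.from_tsv(manifest.proxies_path)
               if manifest.proxies_path else ProxyMap.from_tsv(
                   packaged_data("proxies.tsv")))
    ages = read_tip_ages(manifest.ages_path) if manifest.ages_path else None

    results, errors, run_inputs = {}, {}, {}
    for run in manifest.runs:
        rdir = out / run.id
        rdir.mkdir(exist_ok=True)
        try:
            results[run.id] = _execute_run(run, manifest, matrix, ordered,
                                           ages, rdir)
        except Exception as exc:  # keep going; report at the end
            errors[run.id] = f"{type(exc).__name__}: {exc}"
    report = None
    if results:
        runs_for_report = {
            rid: {"consensus": res["consensus"], "trees": res.get("trees")}
            for rid, res in results.items() if res.get("consensus") is not None}
        report = weak_spot_report(defs, runs_for_report, proxies)
        _write_report(report, out)
    _write_log(manifest, errors, out)
    return {"report": report, "runs": results, "errors": errors}


def _settings_for(run: RunSpec, ordered: frozenset) -> CharacterSettings:
    oset = ordered if run.ordered else frozenset()
    if run.strategy == "IW":
        return CharacterSettings(ordered_set=oset, weighting="IMPLIED",
                                 K=run.K or 3.0)
    return CharacterSettings(ordered_set=oset)


def _execute_run(run: RunSpec, manifest: RunManifest,
                 matrix: CharacterMatrix, ordered: frozenset,
                 ages: Optional[TipCalibration], rdir: Path) -> dict:
    if run.strategy == "BAYES":
        return _execute_bayes(run, manifest, matrix, ages, rdir)
    settings = _settings_for(run, ordered)
    cfg = SearchConfig(n_replicates=manifest.n_replicates, seed=run.seed,
                       root_taxon=manifest.root_taxon,
                       **run.overrides.get("search", {}))
    if run.strategy == "SINGLE_OUTGROUP":
        result = single_outgroup_run(matrix, run.keep_taxon,
                                     manifest.outgroups, settings, cfg)
        used_matrix = matrix.subset_taxa(
            [t for t in matrix.taxa
             if t == run.keep_taxon or t not in manifest.outgroups])
    else:
        result = search_battery(matrix, settings, cfg)
        used_matrix = matrix
    consensus = strict_consensus(list(result))
    write_nexus_trees(list(result), rdir / "trees.nex", with_lengths=False)
    (rdir / "consensus.nwk").write_text(
        consensus.to_newick(with_lengths=False) + "\n")
    scores = {"best_score": result.best_score, "n_trees": len(result),
              "truncated": result.truncated, "strategy": run.strategy,
              "ordered": run.ordered, "K": run.K}
    if settings.weighting == "EQUAL":
        try:
            ci, ri = ensemble_indices(result.best_score, used_matrix, settings)
            scores["CI"] = round(ci, 4)
            scores["RI"] = round(ri, 4)
        except RIUndefinedError:
            from .parsimony import TreeScorer
            scores["CI"] = round(
                TreeScorer(used_matrix, settings).sum_min / result.best_score, 4)
            scores["RI"] = None
    out = {"treeset": result, "trees": list(result), "consensus": consensus,
           "scores": scores}
    if run.strategy == "EQUAL" and run.overrides.get("supports", True):
        out["supports"] = _equal_weight_supports(
            run, manifest, used_matrix, settings, result, rdir)
    (rdir / "scores.json").write_text(json.dumps(scores, indent=2) + "\n")
    return out


def _equal_weight_supports(run, manifest, matrix, settings, result, rdir):
    sup_cfg = SearchConfig(n_replicates=max(manifest.n_replicates // 2, 5),
                           seed=run.seed, root_taxon=manifest.root_taxon)
    bremer = bremer_support(matrix, settings, result, config=sup_cfg)
    boot_cfg = SearchConfig(n_replicates=manifest.bootstrap_search_replicates,
                            seed=run.seed, root_taxon=manifest.root_taxon)
    boots = bootstrap(matrix, settings, boot_cfg,
                      n_reps=manifest.bootstrap_reps, seed=run.seed,
                      clades=list(bremer.clades))
    rows = []
    for clade, sup in bremer.clades.items():
        b = boots.get(clade)
        rows.append({
            "taxa": ";".join(sorted(clade)),
            "DI": sup.bremer_str(),
            "bootstrap": None if b is None else b.bootstrap,
        })
    (rdir / "support.json").write_text(json.dumps(rows, indent=2) + "\n")
    return {"bremer": bremer, "bootstrap": boots, "rows": rows}


def _execute_bayes(run, manifest, matrix, ages, rdir):
    from .tipdating import (ClockModel, MCMCConfig, MkModel, ess, mcct,
                            mcmc_run, sampled_ancestor_histogram)

    if ages is None:
        raise ValueError("Bayesian run needs a tip-age table")
    cfg = MCMCConfig(generations=manifest.bayes_generations,
                     sample_interval=manifest.bayes_sample_interval,
                     seed=run.seed, **run.overrides.get("mcmc", {}))
    sample = mcmc_run(matrix, ages, MkModel(), ClockModel(), cfg)
    post = sample.post_burnin()
    tree = mcct(post)
    half = majority_consensus(post.trees, cutoff=0.5)
    hist, interval = sampled_ancestor_histogram(post)
    ess_values = {k: ess(v) for k, v in post.params.items()
                  if np.asarray(v).std() > 0}
    write_nexus_trees(post.trees, rdir / "posterior_trees.nex")
    (rdir / "mcct.nwk").write_text(tree.to_newick() + "\n")
    (rdir / "half_compact.nwk").write_text(
        half.to_newick(with_lengths=False) + "\n")
    (rdir / "sa_histogram.tsv").write_text(
        "count\tproportion\n"
        + "".join(f"{k}\t{v}\n" for k, v in sorted(hist.items())))
    trace_path = rdir / "trace.tsv"
    names = sorted(post.params)
    with open(trace_path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(len(post)):
            fh.write("\t".join(str(post.params[n][i]) for n in names) + "\n")
    scores = {"sa_interval": list(interval), "ess": ess_values,
              "acceptance": post.acceptance}
    (rdir / "scores.json").write_text(json.dumps(scores, indent=2) + "\n")
    return {"treeset": None, "trees": post.trees, "consensus": tree,
            "half_compact": half, "posterior": post, "scores": scores,
            "sa_histogram": hist, "sa_interval": interval}


def _write_report(report, out: Path) -> None:
    rows = report.to_rows()
    cols = ["name", "run", "status", "applies_fraction", "clade", "reason"]
    with open(out / "weakspots.tsv", "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
    payload = {"summary": report.summary,
               "rows": [{k: v for k, v in r.items()} for r in rows]}
    (out / "weakspots.json").write_text(json.dumps(payload, indent=2) + "\n")


def _write_log(manifest: RunManifest, errors: dict, out: Path) -> None:
    log = {
        "mosaweak_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "n_runs": len(manifest.runs),
        "errors": errors,
    }
    (out / "battery_log.json").write_text(json.dumps(log, indent=2) + "\n")
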