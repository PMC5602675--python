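# mosaweak

Multi-strategy phylogenetic analysis of discrete morphological matrices,
built around the question "which clades survive a change of tree-search
strategy?":

- **Parsimony** scoring (bit-parallel Fitch + generalized Sankoff for
  ordered/additive characters), heuristic search (seeded random addition +
  SPR/TBR with island closure), equal and implied weights (K = 3/6/9-style
  runs), ensemble CI/RI.
- **Supports**: Bremer decay indices via converse-constraint searches,
  nonparametric character bootstrap, strict and majority-rule consensus.
- **Bayesian tip dating**: Mk likelihood conditioned on variable characters
  with discrete-gamma rate variation, a fossilized birth–death tree prior
  with sampled ancestors (extant sampling fixed at zero), MCMC over
  topology/ages/sampled-ancestor placements/parameters, MCCT and
  half-compact consensus summaries, sampled-ancestor histograms, ESS.
- **Clade-definition evaluation**: node- and branch-based ICPN-style
  definitions (with composite and qualifying specifiers), self-destruction
  detection, and a consolidated per-name × per-run *weak-spot report*.
- **Synthetic data**: FBD tree simulator with fossil sampling, Mk/morphocline
  character simulators, and a planted strategy-dependent weak-spot fixture —
  every stage is testable offline.

## CLI

```bash
mosaweak search --matrix m.tnt --ordered chars.txt --weighting equal \
    --replicates 25 --seed 1 --root "Adriosaurus suessi" --out trees.nex
mosaweak support --matrix m.tnt --mode bremer --seed 1 --out support.tsv
mosaweak support --matrix m.tnt --mode bootstrap --reps 500 --seed 1 --out boot.tsv
mosaweak tipdate --matrix m.tnt --ages ages.tsv --generations 1000000 \
    --sample-every 500 --burnin 0.2 --seed 1 --out run/
mosaweak nomenclature --defs table1.json --runs runs.json --out weakspots
mosaweak simulate fixture --seed 1 --out fixture.tnt
mosaweak battery --matrix m.tnt --ages ages.tsv --seed 1 --out results/
```

`mosaweak battery` executes the default twelve-run manifest (2 equal-weights
± ordering, 6 implied-weighting runs at K ∈ {3, 6, 9} × ordering, 3
single-outgroup reruns, 1 Bayesian tip-dating run), computes DI/bootstrap for
the two equal-weights runs only, and writes the consolidated weak-spot
TSV/JSON. A packaged registry of the thirteen clade definitions
(`src/mosaweak/data/table1.json`), the 19-character ordered set, and a
specifier→OTU proxy table are used by default.

## Layout

| module | contents |
| --- | --- |
| `mosaweak.tree` | rooted trees, ages, sampled-ancestor marks, Newick/NEXUS IO |
| `mosaweak.matrix_io` | TNT `xread` reader/writer, tip-age TSV, definition registry |
| `mosaweak.parsimony` | Fitch/Sankoff scoring, step bounds, CI/RI, implied weighting |
| `mosaweak.search` | random addition, SPR/TBR, island closure, constraints, exhaustive oracle |
| `mosaweak.support` | consensus trees, Bremer, bootstrap |
| `mosaweak.definitions` | definition evaluator, proxy map, weak-spot report |
| `mosaweak.tipdating` | Mk likelihood, FBD-SA prior, MCMC, MCCT/ESS/HPD summaries |
| `mosaweak.simulate` | FBD/Mk simulators, weak-spot fixture |
| `mosaweak.pipeline` / `mosaweak.cli` | the twelve-run battery and the `mosaweak` CLI |
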