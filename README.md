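# easigp

Interpretable ensemble genomic prediction with circos visualization of
inferred trait genetic architecture.

`easigp` fits six genomic prediction models — rrBLUP, BayesB, Gaussian-kernel
RKHS, random forest, RBF support-vector regression, and a bipartite graph
attention network — over a grid of train/test prediction scenarios
(population × split ratio × random repeat). For every scenario it records
prediction metrics (Pearson r, MSE), an equal-weight ensemble prediction,
per-marker effect attributions matched to each model family
(allele-substitution coefficients, Shapley values, impurity importance,
integrated gradients), and pairwise marker-by-marker interaction scores from
the forest. Effects are normalized per scenario, averaged across models and
scenarios, and rendered as a layered circos plot: annotation rings, one
decile-shaded ring per model, an ensemble ring, and links for the strongest
interactions.

A built-in simulator generates BC1S4 recombinant-inbred-line populations
(backcross + four selfings, Haldane crossovers) with known additive QTL,
epistatic pairs, replicate structure and target heritability, so the whole
pipeline is testable without external data.

## CLI

```bash
# write a simulated dataset (CSV), genetic map (TSV), annotations, truth JSON
easigp simulate --config sim.yaml --out data/

# run the scenario grid; writes metrics.tsv, effects.tsv, interactions.tsv,
# scenarios.tsv and a manifest
easigp run --config cfg.yaml --out results/

# render the circos plot (SVG + PNG + diffable track/link TSVs)
easigp plot --effects results/effects.tsv --interactions results/interactions.tsv \
    --map data/map.tsv --annotations data/annotations.tsv --out plot.svg

# print the effective configuration with all defaults
easigp show-config
```

Dataset CSV layout: `id,population,replicate,<markers...>,<phenotype>` with
dosages coded 0/1/2 (empty cell = missing). Genetic map TSV:
`marker	chrom	pos_cM`. Annotation TSV:
`track	chrom	start_cM	end_cM	label	pathway`.

Preprocessing mirrors the standard pipeline: markers with >10% missing calls
are dropped and the rest imputed with the per-population modal dosage,
records with missing phenotypes are removed, and markers are LD-pruned
(windowed r² > 0.8, window 30000 markers, step 5) — by default re-run on each
scenario's training set.

## Python API

```python
from easigp import simulate, ensemble, circos

cfg = simulate.SimConfig(n_ril=200, p=100, seed=0)
truth = simulate.TruthArchitecture([15, 70], [1.5, 1.2],
                                   epistatic_pairs=[(30, 85)],
                                   epistatic_effects=[2.5], h2=0.7)
d, truth = simulate.simulate_ril_population(cfg, truth)

scens = ensemble.build_scenarios(["SIM1"], [0.8], n_repeats=10, base_seed=5)
agg = ensemble.run_pipeline(d, scens, models=("rrBLUP", "RF", "RKHS"))
levels = circos.decile_bins(agg.ensemble_effects)
```

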