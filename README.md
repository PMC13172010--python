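# gutnet

Compositional co-occurrence network analysis for gut-microbiome phenotype
studies. The package implements an end-to-end, reproducible pipeline:

1. **Synthetic benchmarks** (`gutnet.synthetic`) — sparse ground-truth
   conditional-dependence graphs (Erdős–Rényi, scale-free, band, modular),
   positive-definite precision matrices with signed edges, and compositional
   count tables under a logistic-normal-multinomial model with log-normal
   sequencing depths.
2. **Phenotype assignment** (`gutnet.phenotype`) — metabolic-health labels
   from fasting glucose, triglycerides, sex-specific HDL, and blood-pressure
   criteria with diagnosis/medication overrides, crossed with the BMI ≥ 30
   obesity threshold to give MHNO / MHO / MUNO / MUO.
3. **Abundance I/O** (`gutnet.abundance`) — MetaPhlAn-style merged profile
   tables, plain samples × taxa TSV, signed weighted edge lists, GraphML;
   prevalence/abundance filtering (default: abundance > 0.1% in ≥ 10% of
   samples) and the centered log-ratio transform.
4. **Network inference** (`gutnet.inference`) — per-taxon L1-penalized
   neighborhood regressions (Meinshausen–Bühlmann) merged with an OR rule,
   penalty selected by StARS stability selection (100 subsamples,
   instability threshold β = 0.05 by default).
5. **Topology** (`gutnet.topology`) — global metrics (order, size, %
   negative edges, density, components) and LCC-restricted means of degree,
   weighted shortest paths (distance = 1 − w), betweenness and closeness;
   k-core histograms; Kruskal–Wallis comparison of node-metric distributions
   with Benjamini–Hochberg correction.
6. **Keystones** (`gutnet.keystones`) — taxa strictly above the 90th
   percentile in both degree and betweenness; ensemble presence/absence
   matrices, set sizes, intersections, core sets, and PCA.
7. **Robustness** (`gutnet.robustness`) — percolation analysis with random
   and targeted node-removal attacks (degree, betweenness, abundance
   ascending/descending), LCC decay curves, the NR50 statistic (% of nodes
   removed at which the LCC first holds ≤ half its original nodes) and the
   percolation threshold p_c (steepest decay-curve slope, flagged undefined
   without a clear phase transition). Attacks run on the positive-edge LCC.
8. **Ensembles** (`gutnet.ensembles`) — repeated group subsampling with
   within-subsample filtering, per-replicate inference/topology/keystones/
   robustness, distribution summaries, rank tests and ranking-consistency
   scores.

## CLI

All stages are exposed through the `gutnet` command:

```sh
gutnet simulate --config config.yaml --out-dir data/sim --seed 1
gutnet classify --metadata subjects.tsv --out labeled.tsv
gutnet analyze  --input abundance.tsv --metadata metadata.tsv --out-dir results/
gutnet attack   network_MHNO.tsv --out-dir robustness/ --strategies degree,betweenness,random
gutnet ensemble --input abundance.tsv --metadata metadata.tsv --out-dir ens/ \
                --subsample-n 100 --n-reps 100
gutnet paired-compare --before t0.tsv --after t1.tsv --out deltas.tsv
```

Configuration is YAML with a versioned schema; unknown keys are rejected and
CLI flags override config values. Output tables carry a provenance header
(`# gutnet <version> / config_hash / seed`).

## Notes on method behavior

CLR-transformed compositions always sum to zero per sample, so an exact
negative linear dependence among columns exists by construction. At desk
scale (tens of taxa) this inflates the share of weak negative edges in
selected networks well above what is seen on real data with hundreds of
taxa; support recovery (F1) on band-graph truth at p = 30, n = 800 is
nevertheless ≥ 0.7 (see `tests/test_acceptance.py`).
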