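# riverpart

**Partitioning a species' range contraction into habitat-modification and
introduced-predation components on river networks.**

Habitat loss and introduced mammalian predators are the two leading drivers
of island bird declines, but they arrived together, so their relative
contributions are confounded in most records.  `riverpart` implements a
landscape-scale way out of that confound for river specialists such as the
whio (*Hymenolaimus malacorhynchos*, blue duck): train a species
distribution model on contemporary occurrences, then compare
suitability-weighted range size under three scenarios — the pre-human
hindcast, the contemporary potential, and the observed occupancy — to read
off each driver's share of the contraction.

The core quantities, per river reach *i* with length *L_i* and modelled
relative likelihood of occurrence RLO:

```text
EH_S            = Σ_i RLO_S(i) · L_i                      effective habitat (km), scenario S
habitat_loss%   = 100 · (1 − EH_contemporary / EH_prehuman)
predation_loss% = 100 · (1 − EH_observed / EH_contemporary)   (additional to habitat loss)
```

computed per bootstrap simulation and summarised mean ± sd.

The package provides, as importable modules and a `riverpart` CLI:

* `riverscape` — a synthetic branching river network with 17 correlated
  reach-scale predictors in two epochs (pre-human / contemporary), known
  ground-truth occupancy, and simulated presence records — so the whole
  pipeline is testable without any proprietary data;
* `sampling` — equal presence/background training data, with background
  drawn from a kernel-density-constrained geographic area;
* `brt` — from-scratch stochastic gradient-boosted regression trees
  (Bernoulli deviance, Newton leaf updates, tree complexity 5, learning
  rate 0.01), ten-fold cross-validated tree selection, AUC and predictive
  deviance, relative influence, partial dependence, pairwise interaction
  strength, and a bootstrapped ensemble with withheld-data diagnostics;
* `scenario` — counterfactual predictor substitution and per-reach
  mean/sd/CV prediction summaries across the ensemble;
* `exdet` — extrapolation detection (univariate NT1, combinational NT2,
  most influential covariate);
* `partition` — effective habitat, the driver partition, and
  estimated-vs-truth recovery reports.

## Worked example

```python
from riverpart import GeneratorConfig, RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=11), out_dir="runs/demo")
r = result.report
print("presence reaches:", r["n_presence_reaches"])
print("CV AUC:", round(r["model"]["cv_auc"], 3))
for name, eh in r["effective_habitat_km"].items():
    print(f"EH {name}: {eh['mean']:.0f} ± {eh['sd']:.0f} km")
p, t = r["partition"], r["truth"]
print(f"habitat loss:   {p['habitat_loss_pct_mean']:.1f} ± {p['habitat_loss_pct_sd']:.1f}%"
      f"   (truth {t['habitat_loss_pct']:.1f}%)")
print(f"predation loss: {p['predation_loss_pct_mean']:.1f} ± {p['predation_loss_pct_sd']:.1f}%"
      f"   (truth {t['predation_loss_pct']:.1f}%)")
```

prints (≈30 s on one CPU; 3,000 reaches, 20 bootstrap members):

```text
presence reaches: 92
CV AUC: 0.937
EH potential_contemporary: 590 ± 13 km
EH potential_prehuman: 887 ± 52 km
EH observed_contemporary: 60 ± 1 km
habitat loss:   33.3 ± 3.2%   (truth 39.0%)
predation loss: 89.9 ± 0.2%   (truth 89.9%)
```

Reading: lowland forest clearance removed about a third of the pre-human
effective habitat, and predation has excluded the species from ~90% of the
habitat that would still be suitable today — close to the known generating
values of the synthetic riverscape.  The run directory contains every stage
artefact as plain CSV/JSON (`reaches.csv`, predictor tables for both
epochs, the training set, per-scenario RLO and ExDet tables, the serialized
ensemble, and `partition_report.json`).

The same run from the shell:

```bash
riverpart run --out runs/demo --seed 11
```

or stage by stage: `riverpart simulate | sample | fit | predict | exdet |
partition`, each reading and writing the run directory.

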